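"""Conformer generation and selection protocols for dynamic cross-docking.

Four protocols produce the (receptor, ligand) conformer pairings handed to a
docking engine:

* P0 — dock the unbound structures as-is: (Ru):(Lu).
* P1 — the naive extremes: deform each partner to its maximum amplitude along
  the lowest nontrivial mode, in both directions, under a secondary-structure
  conservation constraint; 9 pairings.
* P2 — the theoretically best mode combination: project the observed
  unbound->bound displacement onto the lowest three modes (benchmarking only;
  requires the bound complex); 1 pairing.
* P3 — energy-mapped sampling: grid the 3-mode amplitude envelope, score each
  point with a pair potential, normalize scores to [0, 10], and select the
  point farthest from the origin among those with normalized energy <= 5 and
  per-residue secondary-structure conservation >= 90%; 4 pairings.

The maximum-amplitude search starts at +/-100, doubles on success and halves
on failure, then bisects the bracket to a configured tolerance.  "Success"
means the deformed (and minimized) conformation keeps every secondary
structure state within 10 percentage points of the unbound assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from . import secstruct
from .enm import NormalModeSet, deform, project_displacement
from .potential import (PairPotential, SurrogatePotential, build_octree,
                        normalize_energies, total_energy_octree,
                        total_energy_bruteforce, EnergyValue)
from .structure_io import Structure

__all__ = [
    "Minimizer",
    "identity_minimizer",
    "SteepestDescentMinimizer",
    "AmplitudeEnvelope",
    "EnergySample",
    "EnergyMap",
    "CrossDockManifest",
    "P3Selection",
    "amplitude_search",
    "find_max_amplitude",
    "compute_envelope",
    "p1_conformers",
    "p2_conformers",
    "sample_mode_space",
    "select_p3_point",
    "make_manifest",
    "write_energy_map_pdb",
    "read_energy_map_pdb",
]

DEFAULT_INITIAL_AMPLITUDE = 100.0
DEFAULT_AMPLITUDE_CAP = 1600.0  # 100 * 2**4: bounds the doubling phase
DEFAULT_CONVERGENCE_TOL = 1.0
DEFAULT_ENERGY_THRESHOLD = 5.0
DEFAULT_SS_MIN_PCT = 90.0
DEFAULT_SS_TOLERANCE_PCT = 10.0

#: A minimizer is any deterministic Structure -> Structure map preserving atom
#: correspondence (stands in for an external force-field minimization).
Minimizer = Callable[[Structure], Structure]


def identity_minimizer(structure: Structure) -> Structure:
    """The no-op relaxation."""
    return structure


class SteepestDescentMinimizer:
    """Bounded steepest descent on the surrogate potential plus bond restraints.

    A fixed number of fixed-size steps (default 200 steps of 0.01 A along the
    normalized negative gradient) on the built-in 12-6 surrogate energy plus
    harmonic restraints holding consecutive backbone bonds at their input
    lengths.  Entirely deterministic; not a physical force field, just a
    reproducible relaxation satisfying the Minimizer contract.
    """

    def __init__(self, n_steps: int = 200, step_size: float = 0.01,
                 bond_k: float = 20.0, potential: SurrogatePotential | None = None):
        self.n_steps = n_steps
        self.step_size = step_size
        self.bond_k = bond_k
        self.potential = potential or SurrogatePotential(cutoff=8.0)

    def _bond_list(self, structure: Structure) -> np.ndarray:
        bonds = []
        atoms = structure.atoms
        index = {(a.chain_id, a.res_seq, a.i_code, a.name): i for i, a in enumerate(atoms)}
        for (chain, res, icode), idx in structure.residues():
            def find(name, r=res):
                return index.get((chain, r, icode, name))
            n, ca, c, o = (find(x) for x in ("N", "CA", "C", "O"))
            for a, b in ((n, ca), (ca, c), (c, o)):
                if a is not None and b is not None:
                    bonds.append((a, b))
            nxt = index.get((chain, res + 1, icode, "N"))
            if c is not None and nxt is not None:
                bonds.append((c, nxt))
        return np.array(bonds, dtype=int).reshape(-1, 2)

    def __call__(self, structure: Structure) -> Structure:
        coords = structure.coords.copy()
        pot = self.potential
        codes = pot.type_codes(structure)
        from .potential import _exclusion_arrays
        chain_codes, res_seq = _exclusion_arrays(structure)
        bonds = self._bond_list(structure)
        bond_ref = np.linalg.norm(coords[bonds[:, 0]] - coords[bonds[:, 1]], axis=1)
        n = len(coords)
        iu, ju = np.triu_indices(n, k=1)
        nb_mask = ~((chain_codes[iu] == chain_codes[ju])
                    & (np.abs(res_seq[iu] - res_seq[ju]) <= 1))
        iu, ju = iu[nb_mask], ju[nb_mask]
        s = pot._radii[codes[iu]] + pot._radii[codes[ju]]

        for _ in range(self.n_steps):
            grad = np.zeros_like(coords)
            dvec = coords[iu] - coords[ju]
            d = np.linalg.norm(dvec, axis=1)
            within = (d <= pot.cutoff) & (d > 1e-6)
            if np.any(within):
                dd = d[within]
                x6 = (s[within] / dd) ** 6
                # dE/dd of eps[(s/d)^12 - 2(s/d)^6]
                dEdd = -12.0 * pot.epsilon / dd * (x6 * x6 - x6)
                g = (dEdd / dd)[:, None] * dvec[within]
                np.add.at(grad, iu[within], g)
                np.add.at(grad, ju[within], -g)
            bvec = coords[bonds[:, 0]] - coords[bonds[:, 1]]
            bd = np.linalg.norm(bvec, axis=1)
            gb = (2.0 * self.bond_k * (bd - bond_ref) / np.maximum(bd, 1e-9))[:, None] * bvec
            np.add.at(grad, bonds[:, 0], gb)
            np.add.at(grad, bonds[:, 1], -gb)
            norm = np.linalg.norm(grad)
            if norm < 1e-10:
                break
            coords -= self.step_size * grad / norm
        return structure.with_coords(coords)


# ---------------------------------------------------------------------------
# Maximum-amplitude search
# ---------------------------------------------------------------------------

def amplitude_search(passes: Callable[[float], bool],
                     initial: float = DEFAULT_INITIAL_AMPLITUDE,
                     cap: float = DEFAULT_AMPLITUDE_CAP,
                     convergence_tol: float = DEFAULT_CONVERGENCE_TOL) -> float:
    """Largest passing magnitude under a monotone pass criterion.

    Doubles while passing (up to ``cap``), halves while failing, then bisects
    the (pass, fail) bracket until its width is at most ``convergence_tol``.
    Zero deformation always passes, so the pass bound starts at 0.
    """
    if initial <= 0 or cap < initial or convergence_tol <= 0:
        raise ValueError("need 0 < initial <= cap and convergence_tol > 0")
    pass_bound = 0.0
    fail_bound: float | None = None
    a = initial
    while True:
        if passes(a):
            pass_bound = a
            if fail_bound is None:
                if a >= cap:
                    return cap
                a = min(2.0 * a, cap)
                continue
        else:
            fail_bound = a
        if fail_bound - pass_bound <= convergence_tol:
            return pass_bound
        a = 0.5 * (pass_bound + fail_bound)


def find_max_amplitude(structure: Structure, modes: NormalModeSet,
                       mode_index: int, direction: int,
                       minimizer: Minimizer = identity_minimizer,
                       ss_tolerance_pct: float = DEFAULT_SS_TOLERANCE_PCT,
                       *,
                       initial: float = DEFAULT_INITIAL_AMPLITUDE,
                       cap: float = DEFAULT_AMPLITUDE_CAP,
                       convergence_tol: float = DEFAULT_CONVERGENCE_TOL,
                       criterion: Callable[[float], bool] | None = None) -> float:
    """Signed maximum amplitude along one mode under the conservation rule.

    For each trial magnitude ``a`` the structure is deformed by
    ``a * direction`` along ``mode_index``, relaxed by ``minimizer``, and its
    secondary structure compared against the undeformed assignment; the
    conformation passes when no state's percentage moved by more than
    ``ss_tolerance_pct`` points.  ``criterion`` substitutes an arbitrary
    magnitude pass-rule (used for validating the search itself).
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    if criterion is None:
        if not 0 <= mode_index < modes.n_modes:
            raise IndexError(f"mode index {mode_index} out of range 0..{modes.n_modes - 1}")
        reference = secstruct.assign_ss(structure)

        def criterion(a: float) -> bool:
            amplitudes = np.zeros(mode_index + 1)
            amplitudes[mode_index] = a * direction
            candidate = minimizer(deform(structure, modes, amplitudes))
            ok, _ = secstruct.ss_conserved(reference, secstruct.assign_ss(candidate),
                                           ss_tolerance_pct)
            return ok

    magnitude = amplitude_search(criterion, initial=initial, cap=cap,
                                 convergence_tol=convergence_tol)
    return magnitude * direction


@dataclass(frozen=True)
class AmplitudeEnvelope:
    """Per-mode maximum amplitudes: (mode_index, max_positive, max_negative)."""

    limits: tuple

    def __post_init__(self):
        for (k, pos, neg) in self.limits:
            if not (pos >= 0 >= neg):
                raise ValueError(f"mode {k}: need max_positive >= 0 >= max_negative")

    @property
    def n_modes(self) -> int:
        return len(self.limits)


def compute_envelope(structure: Structure, modes: NormalModeSet,
                     minimizer: Minimizer = identity_minimizer,
                     ss_tolerance_pct: float = DEFAULT_SS_TOLERANCE_PCT,
                     n_modes: int | None = None, **search_kwargs) -> AmplitudeEnvelope:
    """Maximum envelope: the per-mode amplitude search run in both directions."""
    n_modes = modes.n_modes if n_modes is None else n_modes
    limits = []
    for k in range(n_modes):
        pos = find_max_amplitude(structure, modes, k, +1, minimizer,
                                 ss_tolerance_pct, **search_kwargs)
        neg = find_max_amplitude(structure, modes, k, -1, minimizer,
                                 ss_tolerance_pct, **search_kwargs)
        limits.append((k, pos, neg))
    return AmplitudeEnvelope(limits=tuple(limits))


# ---------------------------------------------------------------------------
# P1 / P2 conformers
# ---------------------------------------------------------------------------

def p1_conformers(receptor: Structure, ligand: Structure,
                  modes_r: NormalModeSet, modes_l: NormalModeSet,
                  minimizer: Minimizer = identity_minimizer,
                  ss_tolerance_pct: float = DEFAULT_SS_TOLERANCE_PCT,
                  minimize_unbound: bool = False,
                  **search_kwargs) -> dict[str, Structure]:
    """The six P1 conformers {Ru, R+, R-, Lu, L+, L-}.

    R+/R- (and L+/L-) are the minimized deformations at the maximum amplitude
    of the lowest nontrivial mode in each direction; Ru/Lu are the unbound
    inputs (minimized only when ``minimize_unbound``).
    """
    out: dict[str, Structure] = {}
    for prefix, structure, modes in (("R", receptor, modes_r), ("L", ligand, modes_l)):
        out[f"{prefix}u"] = minimizer(structure) if minimize_unbound else structure
        for direction, label in ((+1, "+"), (-1, "-")):
            amp = find_max_amplitude(structure, modes, 0, direction, minimizer,
                                     ss_tolerance_pct, **search_kwargs)
            out[f"{prefix}{label}"] = minimizer(deform(structure, modes, [amp]))
    return out


@dataclass(frozen=True)
class P2Result:
    conformers: dict
    amplitudes: dict


def p2_conformers(receptor_u: Structure, receptor_b, ligand_u: Structure, ligand_b,
                  modes_r: NormalModeSet, modes_l: NormalModeSet,
                  fit_selection: str = "all") -> P2Result:
    """The theoretical-best conformers {R_theor, L_theor} (benchmarking only).

    Each partner's unbound structure is deformed by the closed-form projection
    of its bound displacement onto the retained modes.  No secondary-structure
    gating is applied: the point is the parsimonious unbound->bound route.
    """
    out, amps = {}, {}
    for label, unbound, bound, modes in (("R_theor", receptor_u, receptor_b, modes_r),
                                         ("L_theor", ligand_u, ligand_b, modes_l)):
        beta = project_displacement(modes, unbound, bound, fit_selection=fit_selection)
        out[label] = deform(unbound, modes, beta)
        amps[label] = beta
    return P2Result(conformers=out, amplitudes=amps)


# ---------------------------------------------------------------------------
# P3 energy-mapped sampling and selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergySample:
    """One grid point: mode amplitudes, raw/normalized energy, conservation %."""

    amplitudes: tuple
    energy: EnergyValue
    ss_pct: float

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))


@dataclass(frozen=True)
class EnergyMap:
    """Regular grid over 3 mode amplitudes with normalized sample energies."""

    grid: tuple  # per mode: (min, max, step)
    samples: tuple
    origin_injected: bool = False

    def __post_init__(self):
        counts = 1
        for (lo, hi, step) in self.grid:
            counts *= int(round((hi - lo) / step)) + 1 if step > 0 else 1
        expected = counts + (1 if self.origin_injected else 0)
        if len(self.samples) != expected:
            raise ValueError(
                f"sample count {len(self.samples)} does not cover the grid ({expected})")


def sample_mode_space(structure: Structure, modes: NormalModeSet,
                      envelope: AmplitudeEnvelope,
                      step_counts: Sequence[int],
                      potential: PairPotential,
                      use_octree: bool = True) -> EnergyMap:
    """Score a regular grid over the first three mode amplitudes.

    Every grid point deforms the structure by its amplitude triple (no
    minimization), evaluates the raw pair-potential energy (octree route by
    default) and the per-residue secondary-structure conservation against the
    input, then min-max normalizes all raw energies to [0, 10].  The origin is
    injected as an extra sample when the grid does not contain it, so the
    unbound point is always present.
    """
    if envelope.n_modes != 3 or len(step_counts) != 3:
        raise ValueError("P3 sampling uses exactly 3 modes and 3 step counts")
    if modes.n_modes < 3:
        raise ValueError("mode set must retain at least 3 modes")
    if any(c < 2 for c in step_counts):
        raise ValueError("need at least 2 points per axis")
    axes = []
    for (k, pos, neg), count in zip(envelope.limits, step_counts):
        axes.append(np.linspace(neg, pos, count))
    grid_spec = tuple((float(ax[0]), float(ax[-1]),
                       float(ax[1] - ax[0]) if len(ax) > 1 else 0.0) for ax in axes)
    points = [tuple(float(v) for v in p)
              for p in np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)]
    origin_injected = not any(np.allclose(p, 0.0, atol=1e-12) for p in points)
    if origin_injected:
        points.append((0.0, 0.0, 0.0))

    reference_fp = secstruct.assign_ss(structure)
    raws, ss_pcts = [], []
    for p in points:
        conf = structure if np.allclose(p, 0.0) else deform(structure, modes, np.array(p))
        if use_octree:
            raw = total_energy_octree(conf, potential, build_octree(conf))
        else:
            raw = total_energy_bruteforce(conf, potential)
        if not np.isfinite(raw):
            raise ValueError(f"non-finite energy at grid point {p}")
        raws.append(raw)
        if conf is structure:
            ss_pcts.append(100.0)
        else:
            ss_pcts.append(secstruct.ss_conservation_pct(
                reference_fp, secstruct.assign_ss(conf)))
    normalized = normalize_energies(raws)
    samples = tuple(
        EnergySample(amplitudes=p, energy=EnergyValue(raw=r, normalized=float(nv)),
                     ss_pct=s)
        for p, r, nv, s in zip(points, raws, normalized, ss_pcts))
    return EnergyMap(grid=grid_spec, samples=samples, origin_injected=origin_injected)


@dataclass(frozen=True)
class P3Selection:
    amplitudes: tuple
    sample: EnergySample | None
    fallback_to_origin: bool = False


def select_p3_point(energy_map: EnergyMap,
                    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD,
                    ss_min_pct: float = DEFAULT_SS_MIN_PCT) -> P3Selection:
    """Farthest-from-origin qualifying sample.

    Qualifying samples have normalized energy <= ``energy_threshold`` and
    per-residue conservation >= ``ss_min_pct``; among them the one at maximum
    Euclidean distance from the origin of mode space wins, with ties broken
    by lower normalized energy then lexicographic amplitude order.  If no
    sample qualifies the origin is returned with a fallback flag.
    """
    qualifying = [s for s in energy_map.samples
                  if s.energy.normalized is not None
                  and s.energy.normalized <= energy_threshold
                  and s.ss_pct >= ss_min_pct]
    if not qualifying:
        return P3Selection(amplitudes=(0.0, 0.0, 0.0), sample=None,
                           fallback_to_origin=True)
    qualifying.sort(key=lambda s: (-s.norm, s.energy.normalized, s.amplitudes))
    return P3Selection(amplitudes=qualifying[0].amplitudes, sample=qualifying[0])


# ---------------------------------------------------------------------------
# Manifests and energy-map export
# ---------------------------------------------------------------------------

MANIFEST_PAIRS = {
    "P0": (("Ru", "Lu"),),
    "P1": (("Ru", "Lu"), ("Ru", "L+"), ("Ru", "L-"),
           ("R+", "Lu"), ("R+", "L+"), ("R+", "L-"),
           ("R-", "Lu"), ("R-", "L+"), ("R-", "L-")),
    "P2": (("R_theor", "L_theor"),),
    "P3": (("R5", "L5"), ("Ru", "L5"), ("R5", "Lu"), ("Ru", "Lu")),
}


@dataclass(frozen=True)
class CrossDockManifest:
    """Ordered (receptor conformer, ligand conformer) pairings for one protocol."""

    protocol: str
    pairs: tuple

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("manifest contains duplicate pairs")

    def write_tsv(self, path, paths: dict | None = None) -> None:
        lines = ["receptor\tligand\treceptor_path\tligand_path"]
        for r, l in self.pairs:
            rp = (paths or {}).get(r, "")
            lp = (paths or {}).get(l, "")
            lines.append(f"{r}\t{l}\t{rp}\t{lp}")
        Path(path).write_text("\n".join(lines) + "\n")


def make_manifest(protocol: str) -> CrossDockManifest:
    """Cross-docking pairings for P0 (1), P1 (9), P2 (1) or P3 (4), in canonical order."""
    if protocol not in MANIFEST_PAIRS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {sorted(MANIFEST_PAIRS)}")
    return CrossDockManifest(protocol=protocol, pairs=MANIFEST_PAIRS[protocol])


def write_energy_map_pdb(energy_map: EnergyMap, path) -> None:
    """Export the map in a PDB-like form for 3-D visualization.

    Each sample becomes one pseudo-atom whose x/y/z are the three mode
    amplitudes (divided by a power-of-ten scale when they exceed the PDB
    coordinate columns) and whose B-factor is the normalized energy; REMARK
    lines record the scale and grid specification.
    """
    max_amp = max((max(abs(a) for a in s.amplitudes) for s in energy_map.samples),
                  default=0.0)
    scale = 1.0
    while max_amp / scale > 999.999:
        scale *= 10.0
    lines = [f"REMARK   3 AMPLITUDE SCALE {scale:g}"]
    for k, (lo, hi, step) in enumerate(energy_map.grid):
        lines.append(f"REMARK   3 GRID MODE {k + 1} MIN {lo:g} MAX {hi:g} STEP {step:g}")
    for i, s in enumerate(energy_map.samples, start=1):
        x, y, z = (a / scale for a in s.amplitudes)
        b = s.energy.normalized if s.energy.normalized is not None else 0.0
        lines.append(f"ATOM  {i:>5d}  CA  MAP A{(i - 1) % 9999 + 1:>4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}           C")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_energy_map_pdb(path) -> tuple[float, list[tuple[tuple, float]]]:
    """Recover (scale, [(amplitudes, normalized_b_factor), ...]) from the export."""
    scale = 1.0
    out = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("REMARK   3 AMPLITUDE SCALE"):
            scale = float(line.split()[-1])
        elif line.startswith("ATOM"):
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            b = float(line[60:66])
            out.append(((x * scale, y * scale, z * scale), b))
    return scale, out
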