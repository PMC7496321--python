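"""Synthetic protein backbones and perturbed conformer pairs for self-contained testing.

Every generator is deterministic for a fixed :class:`FixtureSpec` seed.  The
backbones carry the four backbone atoms (N, CA, C, O) per residue with ideal
bond lengths and angles, chained from phi/psi/omega dihedrals; they are meant
to exercise the pipeline (mode computation, secondary-structure assignment,
energy evaluation, pose assessment), not to be physically realistic proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Atom, Structure

__all__ = [
    "FixtureSpec",
    "make_backbone",
    "make_mode_perturbed_pair",
    "make_decoy_pose",
    "place_atom",
]

KINDS = ("helix", "strand", "hairpin", "two_segment_hinge", "complex_pose")

# Ideal backbone internal coordinates (Angstroms / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "coil": (-80.0, 150.0),
}

# Rigid offset of the second hairpin strand relative to the 180-degree-rotated
# first strand (x: registry shift along the strand, y: inter-strand gap).
HAIRPIN_OFFSET = np.array([1.1, 4.8, 0.0])


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure."""

    kind: str
    n_res: int = 12
    seed: int = 0
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.n_res < 3:
            raise ValueError("n_res must be >= 3")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d at distance ``bond`` from c, angle b-c-d, dihedral a-b-c-d."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain(dihedrals: list[tuple[float, float]], chain_id: str = "A",
                 res_name: str = "ALA", first_res_seq: int = 1,
                 serial_start: int = 1) -> list[Atom]:
    """Chain residues from per-residue (phi, psi); omega fixed at 180."""
    n_res = len(dihedrals)
    coords: list[dict[str, np.ndarray]] = []
    # Seed the first residue in a canonical frame.
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        phi, _ = dihedrals[i]
        _, psi_prev = dihedrals[i - 1]
        prev = coords[i - 1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # Carbonyl oxygens: dihedral N-CA-C-O = psi + 180 (O opposite the next N).
    for i in range(n_res):
        _, psi = dihedrals[i]
        r = coords[i]
        r["O"] = place_atom(r["N"], r["CA"], r["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)

    atoms: list[Atom] = []
    serial = serial_start
    for i, r in enumerate(coords):
        for name in ("N", "CA", "C", "O"):
            atoms.append(Atom(serial=serial, name=name, element=name[0],
                              res_name=res_name, chain_id=chain_id,
                              res_seq=first_res_seq + i, i_code="",
                              coord=r[name]))
            serial += 1
    return atoms


def _renumber(atoms: list[Atom], serial_start: int = 1) -> list[Atom]:
    from dataclasses import replace
    return [replace(a, serial=serial_start + i) for i, a in enumerate(atoms)]


def _rigid(atoms: list[Atom], rotation: np.ndarray, translation: np.ndarray) -> list[Atom]:
    from dataclasses import replace
    return [replace(a, coord=rotation @ a.coord + translation) for a in atoms]


def _hairpin_atoms(n_res: int) -> list[Atom]:
    """Two antiparallel strands paired by construction.

    The second strand is the first rotated 180 degrees about the strand (x)
    axis and offset across the pairing direction; the two are bridged by a
    2-residue straight-line turn so the whole fixture is one chain.  The
    offsets are chosen so that backbone carbonyls and amides of facing
    residues sit at hydrogen-bonding distance.
    """
    from dataclasses import replace

    phi, psi = PHI_PSI["strand"]
    strand1 = _build_chain([(phi, psi)] * n_res)
    coords1 = np.array([a.coord for a in strand1])
    center = coords1.mean(axis=0)
    # 180-degree rotation about z reverses the strand direction (x), yielding an
    # antiparallel copy; the offset places it at pairing distance (calibrated so
    # that facing amides/carbonyls fall in hydrogen-bond range).
    rot = np.diag([-1.0, -1.0, 1.0])
    strand2 = _rigid(strand1, rot, center - rot @ center + HAIRPIN_OFFSET)
    turn_len = 2
    out = list(strand1)
    # Straight-line 2-residue turn between strand1 C-terminus and strand2 N-terminus.
    start = strand1[-1].coord
    end = strand2[0].coord
    for t in range(turn_len):
        frac_base = (t + 1) / (turn_len + 1)
        for j, name in enumerate(("N", "CA", "C", "O")):
            frac = frac_base + 0.04 * (j + 1)
            jitter = np.array([0.0, 0.0, 0.6 * (1 if t % 2 == 0 else -1)])
            out.append(Atom(serial=0, name=name, element=name[0], res_name="GLY",
                            chain_id="A", res_seq=n_res + 1 + t, i_code="",
                            coord=start + frac * (end - start) + jitter))
    for a in strand2:
        out.append(replace(a, res_seq=a.res_seq + n_res + turn_len))
    return _renumber(out)


def make_backbone(spec: FixtureSpec) -> Structure:
    """Generate the synthetic backbone described by ``spec``.

    Kinds: ``helix`` / ``strand`` (single ideal segment), ``hairpin`` (two
    antiparallel strands + turn), ``two_segment_hinge`` (helix - 4-residue
    coil - helix), ``complex_pose`` (two helices in contact, chains A and B).
    """
    n = spec.n_res
    if spec.kind in ("helix", "strand"):
        atoms = _build_chain([PHI_PSI[spec.kind]] * n)
    elif spec.kind == "two_segment_hinge":
        dihedrals = ([PHI_PSI["helix"]] * n + [PHI_PSI["coil"]] * 4 + [PHI_PSI["helix"]] * n)
        atoms = _build_chain(dihedrals)
    elif spec.kind == "hairpin":
        atoms = _hairpin_atoms(n)
    elif spec.kind == "complex_pose":
        rec = _build_chain([PHI_PSI["helix"]] * n, chain_id="A")
        lig = _build_chain([PHI_PSI["helix"]] * n, chain_id="B")
        lig = _rigid(lig, np.eye(3), np.array([0.0, 8.5, 0.0]))
        atoms = _renumber(rec + lig)
    else:  # pragma: no cover - guarded by FixtureSpec
        raise ValueError(f"unknown fixture kind {spec.kind!r}")

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        from dataclasses import replace
        noise = rng.normal(0.0, spec.noise_sigma, size=(len(atoms), 3))
        atoms = [replace(a, coord=a.coord + noise[i]) for i, a in enumerate(atoms)]
    return Structure(atoms, id=f"{spec.kind}-{n}-seed{spec.seed}")


def make_mode_perturbed_pair(structure: Structure, modes, amplitudes):
    """Return (unbound, pseudo_bound) where the bound state is an exact mode deformation.

    The displacement lies in the span of ``modes`` by construction, so the
    closed-form projection recovers ``amplitudes`` exactly; this gives a
    ground-truth pair for testing unbound->bound amplitude recovery.
    """
    from .enm import deform
    pseudo_bound = deform(structure, modes, amplitudes)
    return structure, pseudo_bound


def make_decoy_pose(receptor: Structure, ligand: Structure,
                    rotation_deg: float = 0.0,
                    translation=(0.0, 0.0, 0.0),
                    seed: int = 0) -> Structure:
    """Combine receptor and rigidly perturbed ligand into one two-chain pose.

    The ligand is rotated about its own centroid (z axis) by ``rotation_deg``
    and then translated.  Zero rotation and translation reproduces the
    reference pose exactly.
    """
    rec_chains = set(a.chain_id for a in receptor.atoms)
    lig_chains = set(a.chain_id for a in ligand.atoms)
    if rec_chains & lig_chains:
        raise ValueError(f"chain-id clash between receptor and ligand: {rec_chains & lig_chains}")
    theta = np.deg2rad(rotation_deg)
    R = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                  [np.sin(theta), np.cos(theta), 0.0],
                  [0.0, 0.0, 1.0]])
    centroid = ligand.coords.mean(axis=0)
    t = centroid - R @ centroid + np.asarray(translation, dtype=float)
    lig_atoms = _rigid(list(ligand.atoms), R, t)
    atoms = _renumber(list(receptor.atoms) + lig_atoms)
    return Structure(atoms, id=f"pose-{receptor.id}-{ligand.id}")
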