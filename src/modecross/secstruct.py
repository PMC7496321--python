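"""Three-state secondary structure (H/E/C) assignment and conservation criteria.

The assigner is a reduced Kabsch–Sander scheme operating on backbone atoms
only.  Amide hydrogens are reconstructed geometrically (N-H antiparallel to
the preceding residue's C=O), backbone hydrogen bonds are scored with the
electrostatic energy

    E = 0.084 * 332 * (1/d_ON + 1/d_CH - 1/d_OH - 1/d_CN)   [kcal/mol]

with a bond assigned when E < -0.5 kcal/mol.  Helices (H) come from runs of
at least two consecutive i -> i+4 bonds, strands (E) from parallel or
antiparallel bridge ladders of at least two residues; everything else is
coil (C).  This mirrors how full 8-state assignments are collapsed to three
states (all states other than H and E mapped to C) for conservation checks.

Two different conservation statistics are used by the conformer-selection
protocols and are deliberately kept separate:

* :func:`ss_conserved` — the per-state rule: no state's percentage may move
  by more than ``tolerance_pct`` percentage points (default 10).
* :func:`ss_conservation_pct` — per-residue identity: the percentage of
  residues keeping the same state letter (selection requires >= 90).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Structure

__all__ = [
    "SSFingerprint",
    "assign_ss",
    "fingerprint_from_states",
    "ss_conserved",
    "ss_conservation_pct",
]

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q_FACTOR = 0.084 * 332.0


@dataclass(frozen=True)
class SSFingerprint:
    """Per-residue 3-state string plus per-state percentages (sum to 100)."""

    states: str
    pct: dict

    def __post_init__(self):
        if set(self.states) - set("HEC"):
            raise ValueError("states must be over the alphabet {H, E, C}")
        total = sum(self.pct.values())
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"percentages must sum to 100, got {total}")

    def __len__(self):
        return len(self.states)


def fingerprint_from_states(states: str) -> SSFingerprint:
    """Build a fingerprint from an externally supplied 3-state string.

    This is the hook for substituting reference assigner output (e.g. a DSSP
    run collapsed to H/E/C) in place of the built-in assigner.
    """
    states = states.strip().upper()
    if not states:
        raise ValueError("empty state string")
    n = len(states)
    pct = {s: 100.0 * states.count(s) / n for s in "HEC"}
    return SSFingerprint(states=states, pct=pct)


def _backbone_frames(structure: Structure):
    """Per-residue N/CA/C/O coordinates plus reconstructed amide H.

    Raises if any residue lacks a backbone atom.  The amide H of residue i is
    placed 1.0 A from N along the direction of the previous residue's C=O
    bond (O -> C), the standard reconstruction when hydrogens are absent;
    chain-initial residues get no H (they cannot donate).
    """
    residues = structure.residues()
    missing = []
    frames = []
    for key, idx in residues:
        names = {structure.atoms[i].name: structure.atoms[i].coord for i in idx}
        if not all(n in names for n in ("N", "CA", "C", "O")):
            missing.append(key)
            frames.append(None)
        else:
            frames.append({n: names[n] for n in ("N", "CA", "C", "O")})
    if missing:
        raise ValueError(f"residues missing backbone atoms (N, CA, C, O): {missing}")
    keys = [key for key, _ in residues]
    for i, frame in enumerate(frames):
        frame["H"] = None
        if i > 0:
            prev_key, prev = keys[i - 1], frames[i - 1]
            same_chain = prev_key[0] == keys[i][0]
            sequential = keys[i][1] - prev_key[1] in (0, 1)
            if same_chain and sequential:
                co = prev["C"] - prev["O"]
                norm = np.linalg.norm(co)
                if norm > 1e-9:
                    frame["H"] = frame["N"] + co / norm
    return keys, frames


def _hbond_matrix(keys, frames) -> np.ndarray:
    """hb[i, j] is True when the C=O of residue i accepts the N-H of residue j."""
    n = len(frames)
    C = np.array([f["C"] for f in frames])
    O = np.array([f["O"] for f in frames])
    N = np.array([f["N"] for f in frames])
    has_h = np.array([f["H"] is not None for f in frames])
    H = np.array([f["H"] if f["H"] is not None else f["N"] for f in frames])

    d_on = cdist(O, N)
    d_ch = cdist(C, H)
    d_oh = cdist(O, H)
    d_cn = cdist(C, N)
    with np.errstate(divide="ignore"):
        energy = _Q_FACTOR * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)
    hb = energy < HB_ENERGY_CUTOFF
    hb[:, ~has_h] = False
    # Exclude self and sequence neighbours (|i - j| < 2 within a chain).
    for i in range(n):
        for j in range(max(0, i - 1), min(n, i + 2)):
            hb[i, j] = hb[j, i] = False
    # Guard against numerically absurd contacts (clashing reconstructions).
    hb &= d_on < 5.2
    return hb


def _helix_mask(hb: np.ndarray) -> np.ndarray:
    """Residues in alpha-helices: two consecutive i -> i+4 turns mark i+1..i+4."""
    n = hb.shape[0]
    turn = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if hb[i, i + 4]:
            turn[i] = True
    mask = np.zeros(n, dtype=bool)
    for i in range(n - 5):
        if turn[i] and turn[i + 1]:
            mask[i + 1:i + 5] = True
    return mask


def _strand_mask(hb: np.ndarray) -> np.ndarray:
    """Residues in bridge ladders of >= 2 (parallel or antiparallel)."""
    n = hb.shape[0]

    def parallel(i, j):
        return ((0 <= i - 1 and i + 1 < n and hb[i - 1, j] and hb[j, i + 1])
                or (0 <= j - 1 and j + 1 < n and hb[j - 1, i] and hb[i, j + 1]))

    def antiparallel(i, j):
        return ((hb[i, j] and hb[j, i])
                or (0 <= i - 1 and i + 1 < n and 0 <= j - 1 and j + 1 < n
                    and hb[i - 1, j + 1] and hb[j - 1, i + 1]))

    bridges = set()
    for i in range(n):
        for j in range(i + 3, n):
            if parallel(i, j) or antiparallel(i, j):
                bridges.add((i, j))
    mask = np.zeros(n, dtype=bool)
    for (i, j) in bridges:
        for (i2, j2) in ((i + 1, j + 1), (i + 1, j - 1)):
            if (i2, j2) in bridges or (min(i2, j2), max(i2, j2)) in bridges:
                mask[[i, j, i2, j2]] = True
    return mask


def assign_ss(structure: Structure) -> SSFingerprint:
    """Assign H/E/C per residue from backbone geometry (reduced Kabsch–Sander)."""
    keys, frames = _backbone_frames(structure)
    hb = _hbond_matrix(keys, frames)
    helix = _helix_mask(hb)
    strand = _strand_mask(hb)
    states = []
    for i in range(len(frames)):
        if helix[i]:
            states.append("H")  # helix takes priority over bridge membership
        elif strand[i]:
            states.append("E")
        else:
            states.append("C")
    return fingerprint_from_states("".join(states))


def ss_conserved(reference: SSFingerprint, candidate: SSFingerprint,
                 tolerance_pct: float = 10.0):
    """Per-state conservation rule used when searching mode amplitudes.

    True when no state's percentage differs by more than ``tolerance_pct``
    percentage points between the two fingerprints.  Returns
    ``(ok, deltas)`` with the per-state absolute deltas.
    """
    if len(reference) != len(candidate):
        raise ValueError(
            f"residue count mismatch: {len(reference)} vs {len(candidate)}")
    deltas = {s: abs(reference.pct[s] - candidate.pct[s]) for s in "HEC"}
    return all(d <= tolerance_pct for d in deltas.values()), deltas


def ss_conservation_pct(reference: SSFingerprint, candidate: SSFingerprint) -> float:
    """Percentage of residues whose state letter is unchanged."""
    if len(reference) != len(candidate):
        raise ValueError(
            f"residue count mismatch: {len(reference)} vs {len(candidate)}")
    same = sum(a == b for a, b in zip(reference.states, candidate.states))
    return 100.0 * same / len(reference)
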