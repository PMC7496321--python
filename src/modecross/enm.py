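"""Elastic-network normal modes: Hessian construction, mode computation,
deformation along mode combinations, and unbound->bound amplitude projection.

The network is the standard anisotropic elastic network: every heavy atom is a
node, atom pairs within a distance cutoff are joined by identical Hookean
springs, and the 3N x 3N Hessian is assembled from the usual rank-one
super-elements -k (dr dr^T)/|dr|^2.  A connected network has exactly six
zero-frequency modes (rigid translations and rotations); these are discarded
and only the lowest nontrivial modes are retained.

The projection solves, in closed form, for the mode-amplitude combination that
best reproduces an observed conformational change: given the displacement
vector T between superposed bound and unbound coordinates and the retained
mode matrix M (rows = modes), the least-squares amplitudes are
beta = (M M^T)^-1 M T, which for orthonormal modes reduces to beta_i = m_i.T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .structure_io import Structure, superpose

__all__ = [
    "NormalModeSet",
    "build_hessian",
    "compute_modes",
    "deform",
    "project_displacement",
    "DisconnectedNetworkError",
]

DEFAULT_CUTOFF = 8.0
TRIVIAL_EIGENVALUE_RTOL = 1e-8


class DisconnectedNetworkError(ValueError):
    """The elastic network has more than 6 near-zero modes at the given cutoff."""


@dataclass(frozen=True)
class NormalModeSet:
    """Orthonormal nontrivial elastic-network modes bound to a reference structure.

    ``mode_matrix`` is k x 3N with one unit-norm mode per row, eigenvalues
    ascending.  Amplitudes applied to these modes are in Angstroms per unit
    mode vector.
    """

    reference: str
    mode_matrix: np.ndarray
    eigenvalues: np.ndarray
    n_atoms: int
    cutoff: float
    spring_constant: float

    def __post_init__(self):
        M = np.asarray(self.mode_matrix, dtype=float)
        ev = np.asarray(self.eigenvalues, dtype=float)
        if M.ndim != 2 or M.shape[1] != 3 * self.n_atoms:
            raise ValueError("mode_matrix must be k x 3N")
        if len(ev) != M.shape[0]:
            raise ValueError("one eigenvalue per mode required")
        if np.any(np.diff(ev) < -1e-12):
            raise ValueError("eigenvalues must be ascending")
        if np.any(ev <= 1e-10):
            raise ValueError("trivial (near-zero eigenvalue) modes must be excluded")
        G = M @ M.T
        if not np.allclose(G, np.eye(len(ev)), atol=1e-8):
            raise ValueError("modes must be mutually orthonormal")
        object.__setattr__(self, "mode_matrix", M)
        object.__setattr__(self, "eigenvalues", ev)

    @property
    def n_modes(self) -> int:
        return self.mode_matrix.shape[0]

    def displacement(self, amplitudes) -> np.ndarray:
        """N x 3 Cartesian displacement for the given amplitude vector."""
        amplitudes = np.asarray(amplitudes, dtype=float)
        if amplitudes.ndim != 1 or len(amplitudes) > self.n_modes:
            raise ValueError(
                f"amplitude vector of length <= {self.n_modes} required, got shape {amplitudes.shape}")
        flat = amplitudes @ self.mode_matrix[: len(amplitudes)]
        return flat.reshape(self.n_atoms, 3)


def build_hessian(structure: Structure, cutoff: float = DEFAULT_CUTOFF,
                  spring_constant: float = 1.0) -> np.ndarray:
    """Assemble the dense anisotropic-network Hessian (3N x 3N, symmetric PSD)."""
    if structure.n_atoms < 3:
        raise ValueError("elastic network needs at least 3 atoms")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = structure.coords
    n = len(coords)
    dist = squareform(pdist(coords))
    hessian = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero((dist <= cutoff) & (dist > 0))
    mask = ii < jj
    for i, j in zip(ii[mask], jj[mask]):
        dr = coords[j] - coords[i]
        d2 = dr @ dr
        block = -spring_constant * np.outer(dr, dr) / d2
        hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return hessian


def _fix_mode_signs(modes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|component| entry made positive."""
    out = modes.copy()
    for row in out:
        k = int(np.argmax(np.abs(row)))
        if row[k] < 0:
            row *= -1.0
    return out


def compute_modes(structure: Structure, n_modes: int = 3,
                  cutoff: float = DEFAULT_CUTOFF,
                  spring_constant: float = 1.0) -> NormalModeSet:
    """Lowest nontrivial elastic-network modes of ``structure``.

    The six rigid-body modes are removed by an eigenvalue threshold relative to
    the largest eigenvalue; a network yielding any other number of near-zero
    modes (i.e. disconnected at this cutoff) is an error rather than silently
    tolerated.
    """
    n = structure.n_atoms
    if n_modes < 1 or n_modes > 3 * n - 6:
        raise ValueError(f"n_modes must be in [1, 3N-6] = [1, {3 * n - 6}]")
    hessian = build_hessian(structure, cutoff, spring_constant)
    eigenvalues, eigenvectors = eigh(hessian)
    threshold = TRIVIAL_EIGENVALUE_RTOL * max(eigenvalues[-1], 1.0)
    n_trivial = int(np.sum(eigenvalues < threshold))
    if n_trivial > 6:
        raise DisconnectedNetworkError(
            f"{n_trivial} near-zero modes found (expected 6): the network is "
            f"disconnected at cutoff {cutoff} A; try a larger cutoff")
    if n_trivial < 6:
        raise ValueError(f"only {n_trivial} near-zero modes found (expected 6)")
    sel = slice(6, 6 + n_modes)
    modes = eigenvectors[:, sel].T
    modes = modes / np.linalg.norm(modes, axis=1, keepdims=True)
    modes = _fix_mode_signs(modes)
    return NormalModeSet(reference=structure.id, mode_matrix=modes,
                         eigenvalues=eigenvalues[sel], n_atoms=n,
                         cutoff=cutoff, spring_constant=spring_constant)


def deform(structure: Structure, modes: NormalModeSet, amplitudes) -> Structure:
    """Displace coordinates along a linear combination of modes.

    x' = x + sum_i beta_i m_i; atom metadata is preserved.
    """
    if modes.n_atoms != structure.n_atoms:
        raise ValueError(
            f"mode set built for {modes.n_atoms} atoms, structure has {structure.n_atoms}")
    disp = modes.displacement(amplitudes)
    return structure.with_coords(structure.coords + disp)


def project_displacement(modes: NormalModeSet, unbound: Structure, bound,
                         fit_selection: str = "all",
                         method: str = "orthonormal") -> np.ndarray:
    """Closed-form amplitudes of the unbound->bound transition in mode space.

    ``bound`` may be a Structure or an N x 3 coordinate array in one-to-one
    atom correspondence with ``unbound`` (the caller resolves the mapping).
    The bound coordinates are first rigidly superposed onto the unbound frame
    (Kabsch fit on all atoms by default, or on C-alpha atoms with
    ``fit_selection='CA'``); with the all-atom fit a displacement lying in the
    span of the (all-atom) modes leaves the fit exactly at the identity, so
    the projection recovers generating amplitudes exactly.  The residual
    displacement T is then projected onto the modes.  ``method='normal_equations'`` solves the explicit
    (M M^T)^-1 M T system; the default exploits orthonormality (beta_i = m_i.T).
    """
    bound_coords = bound.coords if isinstance(bound, Structure) else np.asarray(bound, dtype=float)
    if bound_coords.shape != (unbound.n_atoms, 3):
        raise ValueError(
            f"bound coordinates must match unbound atom count {unbound.n_atoms}, "
            f"got shape {bound_coords.shape}")
    if modes.n_atoms != unbound.n_atoms:
        raise ValueError("mode set and unbound structure disagree on atom count")
    if fit_selection == "CA":
        idx = unbound.atom_indices(names=("CA",))
        if len(idx) < 3:
            idx = np.arange(unbound.n_atoms)
    elif fit_selection == "all":
        idx = np.arange(unbound.n_atoms)
    else:
        raise ValueError("fit_selection must be 'CA' or 'all'")
    if len(idx) < 3:
        raise ValueError("fewer than 3 paired atoms for superposition")
    sup = superpose(bound_coords[idx], unbound.coords[idx])
    fitted = sup.apply(bound_coords)
    T = (fitted - unbound.coords).ravel()
    M = modes.mode_matrix
    if method == "orthonormal":
        return M @ T
    if method == "normal_equations":
        return np.linalg.solve(M @ M.T, M @ T)
    raise ValueError("method must be 'orthonormal' or 'normal_equations'")


# -- plain-text serialization ------------------------------------------------

def save_modes(modes: NormalModeSet, path) -> None:
    """Write a documented plain-text mode file (header + one block per mode)."""
    with open(path, "w") as fh:
        fh.write(f"# modecross normal modes\n# reference {modes.reference}\n")
        fh.write(f"# n_atoms {modes.n_atoms} n_modes {modes.n_modes} "
                 f"cutoff {modes.cutoff} spring_constant {modes.spring_constant}\n")
        fh.write("# eigenvalues " + " ".join(f"{v:.10g}" for v in modes.eigenvalues) + "\n")
        for k in range(modes.n_modes):
            fh.write(f"MODE {k + 1}\n")
            for row in modes.mode_matrix[k].reshape(modes.n_atoms, 3):
                fh.write(f"{row[0]: .10e} {row[1]: .10e} {row[2]: .10e}\n")


def load_modes(path) -> NormalModeSet:
    reference = ""
    n_atoms = n_modes = 0
    cutoff = spring = 0.0
    eigenvalues: list[float] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# reference"):
                reference = line.split(None, 2)[2].strip()
            elif line.startswith("# n_atoms"):
                parts = line.split()
                n_atoms, n_modes = int(parts[2]), int(parts[4])
                cutoff, spring = float(parts[6]), float(parts[8])
            elif line.startswith("# eigenvalues"):
                eigenvalues = [float(v) for v in line.split()[2:]]
            elif line.startswith(("#", "MODE")):
                continue
            elif line.strip():
                rows.append([float(v) for v in line.split()])
    matrix = np.array(rows).reshape(n_modes, 3 * n_atoms)
    return NormalModeSet(reference=reference, mode_matrix=matrix,
                         eigenvalues=np.array(eigenvalues), n_atoms=n_atoms,
                         cutoff=cutoff, spring_constant=spring)
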