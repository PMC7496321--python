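"""Distance-dependent pair potentials with octree-accelerated cutoff summation.

The total energy of a conformation is the sum of a distance-dependent
atom-pair potential over all unique heavy-atom pairs within a cutoff,
excluding pairs inside the same residue or in sequence-adjacent residues of
the same chain (statistical potentials conventionally exclude bonded and
near-bonded contacts).  Two evaluation routes are provided and must agree
exactly: a brute-force O(N^2) sum (the oracle) and an octree route that
recursively prunes node pairs whose boxes are farther apart than the cutoff.

Two concrete potentials ship with the package: a loader for user-supplied
plain-text distance-binned tables (the format used by published statistical
potentials such as DFIRE-style tables), and a fully documented built-in
surrogate (truncated and shifted 12-6 with per-element radii) so the whole
pipeline runs self-contained.

Energies are relative stabilities in the potential's own units; only
orderings and normalized values in [0, 10] are consumed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Atom, Structure

__all__ = [
    "PairPotential",
    "TablePotential",
    "SurrogatePotential",
    "load_dfire2_table",
    "builtin_surrogate_potential",
    "OctreeNode",
    "build_octree",
    "total_energy_bruteforce",
    "total_energy_octree",
    "normalize_energies",
    "EnergyValue",
    "EvalStats",
]

DEFAULT_LEAF_CAPACITY = 32
DEFAULT_MAX_DEPTH = 12


@dataclass
class EvalStats:
    """Instrumentation: number of candidate atom pairs whose distance was evaluated."""

    pairs_evaluated: int = 0
    unknown_type_pairs: int = 0


@dataclass(frozen=True)
class EnergyValue:
    """A raw potential value and, once a sample set is normalized, its [0, 10] image."""

    raw: float
    normalized: float | None = None

    def __post_init__(self):
        if self.normalized is not None and not (-1e-9 <= self.normalized <= 10.0 + 1e-9):
            raise ValueError(f"normalized energy {self.normalized} outside [0, 10]")


class PairPotential:
    """Contract for distance-dependent atom-pair potentials.

    Subclasses define an atom-typing function and a vectorized energy over
    (type-code pairs, distances).  ``energy_fn`` gives the scalar convenience
    form; all evaluation paths use the vectorized form.
    """

    name: str = "abstract"
    cutoff: float = 0.0

    def atom_type(self, atom: Atom) -> str:
        raise NotImplementedError

    def type_code(self, token: str) -> int:
        """Integer code for a type token; -1 for unknown types."""
        raise NotImplementedError

    def energy_array(self, codes_a: np.ndarray, codes_b: np.ndarray,
                     distances: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- conveniences ------------------------------------------------------

    def energy_fn(self, type_a: str, type_b: str, distance: float) -> float:
        ca, cb = self.type_code(type_a), self.type_code(type_b)
        if ca < 0 or cb < 0:
            raise KeyError(f"unknown atom type in pair ({type_a!r}, {type_b!r})")
        return float(self.energy_array(np.array([ca]), np.array([cb]),
                                       np.array([float(distance)]))[0])

    def type_codes(self, structure: Structure) -> np.ndarray:
        return np.array([self.type_code(self.atom_type(a)) for a in structure.atoms],
                        dtype=int)


class TablePotential(PairPotential):
    """Distance-binned lookup table over typed atom pairs.

    Bins are half-open [lo, hi); distances beyond the last bin (or before the
    first) contribute zero.  The table is symmetrized on load, so
    energy(A, B, d) == energy(B, A, d) always.
    """

    def __init__(self, name: str, bin_edges: np.ndarray, types: list[str],
                 table: np.ndarray, typing: str = "element",
                 unknown_types: str = "skip"):
        if unknown_types not in ("skip", "error"):
            raise ValueError("unknown_types must be 'skip' or 'error'")
        self.name = name
        self.bin_edges = np.asarray(bin_edges, dtype=float)  # length nbins+1
        self.types = list(types)
        self._index = {t: i for i, t in enumerate(self.types)}
        self.table = np.asarray(table, dtype=float)  # ntypes x ntypes x nbins
        self.typing = typing
        self.unknown_types = unknown_types
        self.cutoff = float(self.bin_edges[-1])
        if not np.allclose(self.table, self.table.transpose(1, 0, 2)):
            raise ValueError("table must be symmetric in the two type axes")

    def atom_type(self, atom: Atom) -> str:
        if self.typing == "element":
            return atom.element
        if self.typing == "residue_atom":
            return f"{atom.res_name}_{atom.name}"
        raise ValueError(f"unknown typing scheme {self.typing!r}")

    def type_code(self, token: str) -> int:
        return self._index.get(token, -1)

    def energy_array(self, codes_a, codes_b, distances):
        distances = np.asarray(distances, dtype=float)
        bins = np.searchsorted(self.bin_edges, distances, side="right") - 1
        in_range = (bins >= 0) & (bins < len(self.bin_edges) - 1)
        out = np.zeros_like(distances)
        if np.any(in_range):
            out[in_range] = self.table[codes_a[in_range], codes_b[in_range],
                                       bins[in_range]]
        return out


# Van der Waals radii (A) used by the built-in surrogate.
SURROGATE_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
SURROGATE_DEFAULT_RADIUS = 1.70
SURROGATE_EPSILON = 1.0


class SurrogatePotential(PairPotential):
    """Truncated-and-shifted 12-6 potential with per-element radii.

    E(d) = eps * [(s/d)^12 - 2 (s/d)^6] - E_cut for d <= cutoff, else 0,
    where s = r_a + r_b is the equilibrium separation of the element pair and
    E_cut is the unshifted value at the cutoff, making E continuous there.
    The analytic minimum of the unshifted form is -eps at d = s.
    """

    def __init__(self, cutoff: float = 10.0, epsilon: float = SURROGATE_EPSILON):
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.name = "surrogate-12-6"
        self.cutoff = float(cutoff)
        self.epsilon = float(epsilon)
        self.types = sorted(SURROGATE_RADII) + ["X"]
        self._index = {t: i for i, t in enumerate(self.types)}
        self._radii = np.array([SURROGATE_RADII.get(t, SURROGATE_DEFAULT_RADIUS)
                                for t in self.types])

    def atom_type(self, atom: Atom) -> str:
        return atom.element if atom.element in SURROGATE_RADII else "X"

    def type_code(self, token: str) -> int:
        return self._index.get(token, self._index["X"])

    def pair_minimum(self, elem_a: str, elem_b: str) -> tuple[float, float]:
        """(d_min, E(d_min)) of the shifted form, in closed form."""
        s = (SURROGATE_RADII.get(elem_a, SURROGATE_DEFAULT_RADIUS)
             + SURROGATE_RADII.get(elem_b, SURROGATE_DEFAULT_RADIUS))
        shift = self.epsilon * ((s / self.cutoff) ** 12 - 2 * (s / self.cutoff) ** 6)
        return s, -self.epsilon - shift

    def energy_array(self, codes_a, codes_b, distances):
        distances = np.asarray(distances, dtype=float)
        s = self._radii[codes_a] + self._radii[codes_b]
        d = np.maximum(distances, 1e-6)
        x6 = (s / d) ** 6
        e = self.epsilon * (x6 * x6 - 2 * x6)
        xc6 = (s / self.cutoff) ** 6
        e -= self.epsilon * (xc6 * xc6 - 2 * xc6)
        e[distances > self.cutoff] = 0.0
        return e


def builtin_surrogate_potential(cutoff: float = 10.0) -> SurrogatePotential:
    """The self-contained default potential (see :class:`SurrogatePotential`)."""
    return SurrogatePotential(cutoff=cutoff)


def load_dfire2_table(path: str | Path, typing: str = "element",
                      unknown_types: str = "skip") -> TablePotential:
    """Load a plain-text distance-binned pair-potential table.

    Format: a header line ``#bins lo1 hi1 lo2 hi2 ...`` listing half-open bin
    edges, then one row per type pair: ``TYPE_A TYPE_B e1 e2 ...``.  Pairs are
    symmetrized; a pair given in both orders must agree.  ``typing`` selects
    how structure atoms map to the table's type tokens (``element`` or
    ``residue_atom`` for RES_NAME tokens).
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("##")]
    if not lines or not lines[0].startswith("#bins"):
        raise ValueError(f"{path}: missing '#bins' header line")
    edge_values = [float(v) for v in lines[0].split()[1:]]
    if len(edge_values) < 2 or len(edge_values) % 2 != 0:
        raise ValueError(f"{path}: bin header must list lo/hi pairs")
    lows, highs = edge_values[0::2], edge_values[1::2]
    for k in range(len(lows) - 1):
        if highs[k] != lows[k + 1]:
            raise ValueError(f"{path}: bins must be contiguous ([lo, hi) edges)")
    edges = np.array(lows + [highs[-1]])
    n_bins = len(lows)

    entries: dict[tuple[str, str], list[float]] = {}
    types: list[str] = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 2 + n_bins:
            raise ValueError(f"{path}: row {ln!r} must have 2 types + {n_bins} energies")
        a, b = parts[0], parts[1]
        values = [float(v) for v in parts[2:]]
        key = (min(a, b), max(a, b))
        if key in entries and entries[key] != values:
            raise ValueError(f"{path}: conflicting duplicate entry for pair {a}/{b}")
        entries[key] = values
        for t in (a, b):
            if t not in types:
                types.append(t)
    if not entries:
        raise ValueError(f"{path}: table has no rows")
    n = len(types)
    table = np.zeros((n, n, n_bins))
    index = {t: i for i, t in enumerate(types)}
    for (a, b), values in entries.items():
        ia, ib = index[a], index[b]
        table[ia, ib] = table[ib, ia] = values
    return TablePotential(name=path.stem, bin_edges=edges, types=types,
                          table=table, typing=typing, unknown_types=unknown_types)


# ---------------------------------------------------------------------------
# Pair enumeration and summation
# ---------------------------------------------------------------------------

def _exclusion_arrays(structure: Structure):
    """Per-atom chain codes and residue numbers for near-bonded exclusion."""
    chains = {c: i for i, c in enumerate(structure.chain_ids())}
    chain_codes = np.array([chains[a.chain_id] for a in structure.atoms], dtype=int)
    res_seq = np.array([a.res_seq for a in structure.atoms], dtype=int)
    return chain_codes, res_seq


def _block_energy(potential: PairPotential, coords, codes, chain_codes, res_seq,
                  idx_a: np.ndarray, idx_b: np.ndarray, stats: EvalStats | None):
    """Energy over the cartesian product idx_a x idx_b (or the i<j upper
    triangle when the two index sets are identical)."""
    same = idx_a is idx_b
    d = cdist(coords[idx_a], coords[idx_b])
    if same:
        iu, ju = np.triu_indices(len(idx_a), k=1)
        ai, bj = idx_a[iu], idx_b[ju]
        dist = d[iu, ju]
    else:
        ai = np.repeat(idx_a, len(idx_b))
        bj = np.tile(idx_b, len(idx_a))
        dist = d.ravel()
    if stats is not None:
        stats.pairs_evaluated += len(dist)
    keep = dist <= potential.cutoff
    # Near-bonded exclusion: same residue or adjacent residues in one chain.
    keep &= ~((chain_codes[ai] == chain_codes[bj])
              & (np.abs(res_seq[ai] - res_seq[bj]) <= 1))
    ca, cb = codes[ai], codes[bj]
    known = (ca >= 0) & (cb >= 0)
    if stats is not None:
        stats.unknown_type_pairs += int(np.sum(keep & ~known))
    keep &= known
    if not np.any(keep):
        return 0.0
    return float(np.sum(potential.energy_array(ca[keep], cb[keep], dist[keep])))


def total_energy_bruteforce(structure: Structure, potential: PairPotential,
                            stats: EvalStats | None = None) -> float:
    """O(N^2) reference sum over all unique atom pairs (the oracle route)."""
    codes = potential.type_codes(structure)
    if getattr(potential, "unknown_types", "skip") == "error" and np.any(codes < 0):
        raise KeyError("structure contains atom types unknown to the potential")
    chain_codes, res_seq = _exclusion_arrays(structure)
    idx = np.arange(structure.n_atoms)
    return _block_energy(potential, structure.coords, codes, chain_codes, res_seq,
                         idx, idx, stats)


# ---------------------------------------------------------------------------
# Octree
# ---------------------------------------------------------------------------

@dataclass
class OctreeNode:
    """Axis-aligned box node; leaves own disjoint atom index lists."""

    lo: np.ndarray
    hi: np.ndarray
    depth: int
    children: list = field(default_factory=list)
    atom_indices: np.ndarray | None = None
    n_atoms_total: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def min_distance(self, other: "OctreeNode") -> float:
        """Minimum distance between the two boxes (0 if they overlap)."""
        gap = np.maximum(0.0, np.maximum(other.lo - self.hi, self.lo - other.hi))
        return float(np.linalg.norm(gap))


def build_octree(structure: Structure, capacity: int = DEFAULT_LEAF_CAPACITY,
                 max_depth: int = DEFAULT_MAX_DEPTH,
                 padding: float = 0.0) -> OctreeNode:
    """Recursive 8-way partition of the structure's bounding box.

    Splitting stops when a node holds at most ``capacity`` atoms or reaches
    ``max_depth``.  ``padding`` grows the root box (e.g. by one cutoff
    length) without affecting correctness.
    """
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    coords = structure.coords
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    hi = np.maximum(hi, lo + 1e-6)  # avoid zero-thickness boxes

    def split(lo, hi, idx, depth):
        node = OctreeNode(lo=lo, hi=hi, depth=depth, n_atoms_total=len(idx))
        if len(idx) <= capacity or depth >= max_depth:
            node.atom_indices = idx
            return node
        mid = 0.5 * (lo + hi)
        side = coords[idx] > mid  # boolean octant key per atom
        octant = side[:, 0] * 4 + side[:, 1] * 2 + side[:, 2] * 1
        for k in range(8):
            sub = idx[octant == k]
            if len(sub) == 0:
                continue
            bits = np.array([k >> 2 & 1, k >> 1 & 1, k & 1], dtype=bool)
            c_lo = np.where(bits, mid, lo)
            c_hi = np.where(bits, hi, mid)
            node.children.append(split(c_lo, c_hi, sub, depth + 1))
        return node

    return split(lo, hi, np.arange(len(coords)), 0)


def total_energy_octree(structure: Structure, potential: PairPotential,
                        tree: OctreeNode | None = None,
                        stats: EvalStats | None = None) -> float:
    """Cutoff-pruned pair sum over octree node pairs.

    Node pairs whose box-box minimum distance exceeds the cutoff cannot
    contribute and are skipped; the surviving leaf-pair (and leaf-self)
    blocks enumerate exactly the brute-force pair set, so the result matches
    :func:`total_energy_bruteforce` to floating-point accumulation order.
    """
    if tree is None:
        tree = build_octree(structure)
    if tree.n_atoms_total != structure.n_atoms:
        raise ValueError(
            f"octree built for {tree.n_atoms_total} atoms, structure has {structure.n_atoms}")
    codes = potential.type_codes(structure)
    chain_codes, res_seq = _exclusion_arrays(structure)
    coords = structure.coords
    cutoff = potential.cutoff
    total = 0.0

    stack_pairs: list[tuple[OctreeNode, OctreeNode]] = []
    stack_self: list[OctreeNode] = [tree]
    while stack_self:
        node = stack_self.pop()
        if node.is_leaf:
            total += _block_energy(potential, coords, codes, chain_codes, res_seq,
                                   node.atom_indices, node.atom_indices, stats)
        else:
            stack_self.extend(node.children)
            for i, a in enumerate(node.children):
                for b in node.children[i + 1:]:
                    stack_pairs.append((a, b))
    while stack_pairs:
        a, b = stack_pairs.pop()
        if a.min_distance(b) > cutoff:
            continue
        if a.is_leaf and b.is_leaf:
            total += _block_energy(potential, coords, codes, chain_codes, res_seq,
                                   a.atom_indices, b.atom_indices, stats)
        else:
            # Split the node with more atoms (ties: the non-leaf one).
            if b.is_leaf or (not a.is_leaf and a.n_atoms_total >= b.n_atoms_total):
                for c in a.children:
                    stack_pairs.append((c, b))
            else:
                for c in b.children:
                    stack_pairs.append((a, c))
    return total


def normalize_energies(raw_values) -> np.ndarray:
    """Min-max map to [0, 10]: v -> 10 (v - min) / (max - min).

    The lowest raw value maps to 0.0 and the highest to 10.0; a constant
    input maps everything to 0.0 by convention.
    """
    values = np.asarray(raw_values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalize an empty value list")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite energy values cannot be normalized")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return 10.0 * (values - lo) / (hi - lo)
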