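"""Structural data model, fixed-column PDB input/output and rigid-body superposition.

The :class:`Structure` is the unit passed between every stage of the pipeline:
an ordered list of atoms with chain/residue identity and Cartesian coordinates
in Angstroms.  Internal indexing is 0-based; residue numbers are kept 1-based
as read from the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Superposition",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "superpose",
    "apply_superposition",
    "kabsch",
]

# Two-letter element symbols that appear in protein/hetero chemistry; used when
# deriving the element from the atom name of a record lacking columns 77-78.
_TWO_LETTER_ELEMENTS = {
    "BR", "CL", "FE", "MG", "MN", "ZN", "CA", "NA", "CU", "NI", "CO", "SE", "CD", "HG",
}


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class Atom:
    """One atom record: identity plus Cartesian coordinates in Angstroms."""

    serial: int
    name: str
    element: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.serial} {self.name!r}: coord must be a finite 3-vector")
        if not self.name:
            raise ValueError(f"atom {self.serial}: empty atom name")
        object.__setattr__(self, "coord", coord)

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.i_code)

    def is_backbone(self) -> bool:
        return self.name in ("N", "CA", "C", "O")

    def is_heavy(self) -> bool:
        return self.element != "H"


def _derive_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2].upper() in _TWO_LETTER_ELEMENTS and len(stripped) > 1 and stripped.isalpha():
        # Protein backbone/sidechain names like "CA" (alpha carbon) collide with
        # calcium; inside polymer atoms we prefer the single-letter reading.
        return stripped[0].upper()
    return stripped[0].upper()


@dataclass
class Structure:
    """Ordered atom list with uniqueness of (chain, res_seq, i_code, name)."""

    atoms: list[Atom]
    id: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")
        seen: set[tuple] = set()
        for atom in self.atoms:
            key = (atom.chain_id, atom.res_seq, atom.i_code, atom.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in structure {self.id!r}")
            seen.add(key)
        self._invalidate_cache()

    def _invalidate_cache(self):
        self._coords: np.ndarray | None = None

    # -- array views -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """N x 3 coordinate array (a fresh copy each call is avoided; do not mutate)."""
        if getattr(self, "_coords", None) is None:
            self._coords = np.array([a.coord for a in self.atoms], dtype=float)
        return self._coords

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """Return a copy of this structure with replaced coordinates (same atoms)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords of shape ({self.n_atoms}, 3), got {coords.shape}")
        atoms = [replace(a, coord=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms, id=self.id if id is None else id)

    # -- selections --------------------------------------------------------

    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def atom_indices(self, names: Sequence[str] | None = None,
                     chains: Iterable[str] | None = None) -> np.ndarray:
        chains = set(chains) if chains is not None else None
        idx = [
            i for i, a in enumerate(self.atoms)
            if (names is None or a.name in names) and (chains is None or a.chain_id in chains)
        ]
        return np.asarray(idx, dtype=int)

    def select(self, names: Sequence[str] | None = None,
               chains: Iterable[str] | None = None) -> "Structure":
        idx = self.atom_indices(names=names, chains=chains)
        if len(idx) == 0:
            raise ValueError("selection matched no atoms")
        return Structure([self.atoms[i] for i in idx], id=self.id)

    def residues(self) -> list[tuple[tuple[str, int, str], list[int]]]:
        """Atom indices grouped by residue, preserving file order."""
        order: list[tuple[str, int, str]] = []
        groups: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            key = a.residue_id
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(i)
        return [(key, groups[key]) for key in order]

    @property
    def n_residues(self) -> int:
        return len({a.residue_id for a in self.atoms})


@dataclass(frozen=True)
class Superposition:
    """Rigid transform (proper rotation + translation) and the resulting RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be a proper 3x3 orthonormal matrix")
        if self.rmsd < 0:
            raise ValueError("rmsd must be nonnegative")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str]:
    """Parse one ATOM/HETATM record; returns (atom, altloc)."""
    line = line.rstrip("\n")
    if len(line) < 54:
        raise PDBParseError("ATOM record shorter than coordinate fields", lineno)
    try:
        serial = int(line[6:11])
    except ValueError:
        raise PDBParseError(f"bad serial field {line[6:11]!r}", lineno) from None
    name = line[12:16].strip()
    altloc = line[16].strip()
    res_name = line[17:20].strip()
    chain_id = line[21]
    try:
        res_seq = int(line[22:26])
    except ValueError:
        raise PDBParseError(f"bad residue number field {line[22:26]!r}", lineno) from None
    i_code = line[26].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        raise PDBParseError(f"bad coordinate fields {line[30:54]!r}", lineno) from None

    def _float_field(lo, hi, default):
        text = line[lo:hi].strip()
        if not text:
            return default
        try:
            return float(text)
        except ValueError:
            raise PDBParseError(f"bad numeric field {text!r}", lineno) from None

    occupancy = _float_field(54, 60, 1.0)
    b_factor = _float_field(60, 66, 0.0)
    element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
    if not element:
        element = _derive_element(name)
    atom = Atom(serial=serial, name=name, element=element, res_name=res_name,
                chain_id=chain_id, res_seq=res_seq, i_code=i_code,
                coord=np.array([x, y, z]), occupancy=occupancy, b_factor=b_factor)
    return atom, altloc


def read_pdb(path: str | Path, model_index: int = 0, *,
             include_hetatm: bool = False, id: str | None = None) -> Structure:
    """Read a fixed-column PDB file into a :class:`Structure`.

    ``model_index`` selects a MODEL block (0-based) in multi-model files; files
    without MODEL records are treated as a single model 0.  HETATM records are
    skipped unless ``include_hetatm``.  For alternate locations only the
    highest-occupancy conformer is kept, ties broken in favour of altloc 'A'
    (then alphabetically).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")

    current_model = 0
    in_wanted_model = model_index == 0
    saw_model_records = False
    # key -> (atom, altloc); altloc dedup by (chain, res_seq, i_code, name)
    chosen: dict[tuple, tuple[Atom, str]] = {}
    order: list[tuple] = []

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "MODEL ":
                saw_model_records = True
                try:
                    current_model = int(line[6:].split()[0]) - 1
                except (ValueError, IndexError):
                    current_model += 1
                in_wanted_model = current_model == model_index
                continue
            if record == "ENDMDL":
                in_wanted_model = False
                continue
            if record not in ("ATOM  ", "HETATM"):
                continue
            if not in_wanted_model:
                continue
            if record == "HETATM" and not include_hetatm:
                continue
            atom, altloc = _parse_atom_line(line, lineno)
            key = (atom.chain_id, atom.res_seq, atom.i_code, atom.name)
            if key not in chosen:
                chosen[key] = (atom, altloc)
                order.append(key)
            else:
                prev_atom, prev_alt = chosen[key]
                better = (atom.occupancy > prev_atom.occupancy
                          or (atom.occupancy == prev_atom.occupancy
                              and (altloc or "~") < (prev_alt or "~")))
                if better:
                    chosen[key] = (atom, altloc)

    if not chosen:
        if saw_model_records and model_index != 0:
            raise ValueError(f"{path}: no atoms in model index {model_index}")
        raise ValueError(f"{path}: no atoms (file contains no usable ATOM records)")
    atoms = [chosen[k][0] for k in order]
    return Structure(atoms, id=id if id is not None else path.stem)


def _format_atom_line(atom: Atom, serial: int) -> str:
    name = atom.name
    # PDB alignment rule: 1-letter elements start in column 14 unless 4 chars.
    if len(name) < 4 and len(atom.element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    x, y, z = atom.coord
    return (f"ATOM  {serial:>5d} {name_field} {atom.res_name:<3s} {atom.chain_id}"
            f"{atom.res_seq:>4d}{atom.i_code or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
            f"          {atom.element:>2s}")


def write_pdb(structure: Structure, path: str | Path,
              remarks: Sequence[str] = ()) -> None:
    """Write fixed-column ATOM records with TER between chains and a final END."""
    path = Path(path)
    lines: list[str] = [f"REMARK   3 {text}" for text in remarks]
    serial = 0
    prev_chain: str | None = None
    prev_atom: Atom | None = None
    for atom in structure.atoms:
        if prev_chain is not None and atom.chain_id != prev_chain:
            serial += 1
            lines.append(f"TER   {serial:>5d}      {prev_atom.res_name:<3s} "
                         f"{prev_atom.chain_id}{prev_atom.res_seq:>4d}")
        serial += 1
        lines.append(_format_atom_line(atom, serial))
        prev_chain = atom.chain_id
        prev_atom = atom
    serial += 1
    lines.append(f"TER   {serial:>5d}      {prev_atom.res_name:<3s} "
                 f"{prev_atom.chain_id}{prev_atom.res_seq:>4d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t mapping mobile onto target.

    Solves min_R,t sum_i |R x_i + t - y_i|^2 by SVD of the covariance matrix,
    with the reflection corrected so det(R) = +1.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return R, t


def superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Optimal rigid superposition of two paired coordinate sets (Kabsch).

    Requires >= 3 paired, non-collinear points.  The returned transform maps
    ``mobile`` onto ``target``; ``rmsd`` is evaluated after applying it.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"point count mismatch: {mobile.shape} vs {target.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 paired 3-D points")
    centered = mobile - mobile.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    R, t = kabsch(mobile, target)
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def apply_superposition(structure: Structure, sup: Superposition) -> Structure:
    return structure.with_coords(sup.apply(structure.coords))
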