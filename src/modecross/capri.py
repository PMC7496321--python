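"""CAPRI-style assessment of docked poses against a reference complex.

Metrics follow the community assessment conventions: FNAT (fraction of the
reference's interface residue contacts reproduced by the model, contacts at
5 A between heavy atoms), FNONNAT (fraction of model contacts absent from the
reference), LRMSD (backbone RMSD of the ligand after superposing the model's
receptor backbone onto the reference's), and IRMSD (backbone RMSD over
reference interface residues — any atom within 10 A of the partner — after
optimal superposition of those interface backbones).  Quality classes:

* High:       fnat >= 0.5 and (lrmsd <= 1.0 or irmsd <= 1.0)
* Medium:     fnat >= 0.3 and (lrmsd <= 5.0 or irmsd <= 2.0), not High
* Acceptable: fnat >= 0.1 and (lrmsd <= 10.0 or irmsd <= 4.0), not Medium/High
* Incorrect:  otherwise

All inequalities are non-strict.  Target difficulty from the unbound-bound
interface C-alpha RMSD: rigid-body (RB) <= 1.35 A, medium (M) in (1.35, 2.5],
difficult (D) > 2.5 A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Structure, superpose

__all__ = [
    "CapriMetrics",
    "ContactSet",
    "native_contacts",
    "assess_pose",
    "classify_quality",
    "classify_difficulty",
    "interface_ca_rmsd",
]

CONTACT_CUTOFF = 5.0
INTERFACE_CUTOFF = 10.0
BACKBONE = ("N", "CA", "C", "O")

ContactSet = frozenset  # of ((chain, res_seq, i_code), (chain, res_seq, i_code))


@dataclass(frozen=True)
class CapriMetrics:
    """FNAT/FNONNAT/LRMSD/IRMSD plus the four-class quality label."""

    fnat: float
    fnonnat: float
    lrmsd: float
    irmsd: float
    quality: str

    def __post_init__(self):
        if not (0.0 <= self.fnat <= 1.0 and 0.0 <= self.fnonnat <= 1.0):
            raise ValueError("fnat/fnonnat must lie in [0, 1]")
        if self.lrmsd < 0 or self.irmsd < 0:
            raise ValueError("RMSDs must be nonnegative")
        if self.quality not in ("High", "Medium", "Acceptable", "Incorrect"):
            raise ValueError(f"unknown quality label {self.quality!r}")


def _partition(structure: Structure, receptor_chains: Iterable[str],
               ligand_chains: Iterable[str]):
    receptor_chains, ligand_chains = set(receptor_chains), set(ligand_chains)
    if not receptor_chains or not ligand_chains:
        raise ValueError("both chain sets must be nonempty")
    if receptor_chains & ligand_chains:
        raise ValueError("receptor and ligand chain sets must be disjoint")
    present = set(structure.chain_ids())
    unknown = (receptor_chains | ligand_chains) - present
    if unknown:
        raise ValueError(f"chains {sorted(unknown)} not present in structure "
                         f"(has {sorted(present)})")
    return receptor_chains, ligand_chains


def native_contacts(complex_structure: Structure, receptor_chains: Iterable[str],
                    ligand_chains: Iterable[str],
                    cutoff: float = CONTACT_CUTOFF) -> ContactSet:
    """Residue pairs with any heavy-atom pair within ``cutoff`` across the interface."""
    receptor_chains, ligand_chains = _partition(complex_structure,
                                                receptor_chains, ligand_chains)
    rec_idx = [i for i, a in enumerate(complex_structure.atoms)
               if a.chain_id in receptor_chains and a.is_heavy()]
    lig_idx = [i for i, a in enumerate(complex_structure.atoms)
               if a.chain_id in ligand_chains and a.is_heavy()]
    coords = complex_structure.coords
    d = cdist(coords[rec_idx], coords[lig_idx])
    pairs = set()
    ri, lj = np.nonzero(d <= cutoff)
    for i, j in zip(ri, lj):
        pairs.add((complex_structure.atoms[rec_idx[i]].residue_id,
                   complex_structure.atoms[lig_idx[j]].residue_id))
    return frozenset(pairs)


def classify_quality(fnat: float, lrmsd: float, irmsd: float) -> str:
    if fnat >= 0.5 and (lrmsd <= 1.0 or irmsd <= 1.0):
        return "High"
    if fnat >= 0.3 and (lrmsd <= 5.0 or irmsd <= 2.0):
        return "Medium"
    if fnat >= 0.1 and (lrmsd <= 10.0 or irmsd <= 4.0):
        return "Acceptable"
    return "Incorrect"


def _matched_indices(model: Structure, reference: Structure, chains: set[str],
                     names: tuple[str, ...] | None, heavy_only: bool = False):
    """Indices of atoms present in both structures, matched by (residue id, name)."""
    def keyed(structure):
        return {
            (a.residue_id, a.name): i for i, a in enumerate(structure.atoms)
            if a.chain_id in chains
            and (names is None or a.name in names)
            and (not heavy_only or a.is_heavy())
        }
    mk, rk = keyed(model), keyed(reference)
    common = sorted(set(mk) & set(rk))
    return ([mk[k] for k in common], [rk[k] for k in common])


def assess_pose(model: Structure, reference: Structure,
                receptor_chains: Iterable[str], ligand_chains: Iterable[str],
                contact_cutoff: float = CONTACT_CUTOFF,
                interface_cutoff: float = INTERFACE_CUTOFF) -> CapriMetrics:
    """Score one docked pose against the reference complex.

    Residues are matched between model and reference by (chain, residue
    number, insertion code); residues present in only one of the two are
    dropped from the RMSD atom sets.
    """
    receptor_chains, ligand_chains = _partition(reference, receptor_chains,
                                                ligand_chains)
    native = native_contacts(reference, receptor_chains, ligand_chains,
                             contact_cutoff)
    if not native:
        raise ValueError("reference has no inter-chain contacts: not a complex")
    model_contacts = native_contacts(model, receptor_chains, ligand_chains,
                                     contact_cutoff)
    fnat = len(model_contacts & native) / len(native)
    fnonnat = (len(model_contacts - native) / len(model_contacts)
               if model_contacts else 0.0)

    # LRMSD: superpose receptor backbones, measure ligand backbone deviation.
    rec_m, rec_r = _matched_indices(model, reference, receptor_chains, BACKBONE)
    lig_m, lig_r = _matched_indices(model, reference, ligand_chains, BACKBONE)
    if len(rec_m) < 3 or len(lig_m) < 1:
        raise ValueError("insufficient residue correspondence between model and reference")
    sup = superpose(model.coords[rec_m], reference.coords[rec_r])
    moved_lig = sup.apply(model.coords[lig_m])
    lrmsd = float(np.sqrt(np.mean(np.sum((moved_lig - reference.coords[lig_r]) ** 2,
                                         axis=1))))

    # IRMSD: backbone RMSD over reference interface residues, optimally fitted.
    interface = _interface_residues(reference, receptor_chains, ligand_chains,
                                    interface_cutoff)
    int_m, int_r = [], []
    for mi, ri in zip(*_matched_indices(model, reference,
                                        receptor_chains | ligand_chains, BACKBONE)):
        if reference.atoms[ri].residue_id in interface:
            int_m.append(mi)
            int_r.append(ri)
    if len(int_m) < 3:
        raise ValueError("fewer than 3 matched interface backbone atoms")
    irmsd = superpose(model.coords[int_m], reference.coords[int_r]).rmsd

    quality = classify_quality(fnat, lrmsd, irmsd)
    return CapriMetrics(fnat=fnat, fnonnat=fnonnat, lrmsd=lrmsd, irmsd=irmsd,
                        quality=quality)


def _interface_residues(reference: Structure, receptor_chains, ligand_chains,
                        cutoff: float) -> set:
    """Residues with any atom within ``cutoff`` of the partner (reference frame)."""
    rec_idx = [i for i, a in enumerate(reference.atoms) if a.chain_id in receptor_chains]
    lig_idx = [i for i, a in enumerate(reference.atoms) if a.chain_id in ligand_chains]
    coords = reference.coords
    d = cdist(coords[rec_idx], coords[lig_idx])
    residues = set()
    ri, lj = np.nonzero(d <= cutoff)
    for i in set(ri):
        residues.add(reference.atoms[rec_idx[i]].residue_id)
    for j in set(lj):
        residues.add(reference.atoms[lig_idx[j]].residue_id)
    return residues


def interface_ca_rmsd(unbound: Structure, bound: Structure, partner_bound: Structure,
                      cutoff: float = INTERFACE_CUTOFF) -> float:
    """Unbound-bound interface C-alpha RMSD (the difficulty-table statistic).

    Interface residues are those of ``bound`` with any atom within ``cutoff``
    of ``partner_bound``; their C-alpha atoms, matched to ``unbound`` by
    residue id, are optimally superposed and the RMSD returned.
    """
    coords_b = bound.coords
    d = cdist(coords_b, partner_bound.coords)
    near = d.min(axis=1) <= cutoff
    iface = {bound.atoms[i].residue_id for i in np.nonzero(near)[0]}
    keyed_u = {a.residue_id: i for i, a in enumerate(unbound.atoms) if a.name == "CA"}
    keyed_b = {a.residue_id: i for i, a in enumerate(bound.atoms) if a.name == "CA"}
    common = sorted((set(keyed_u) & set(keyed_b)) & iface)
    if len(common) < 3:
        raise ValueError("fewer than 3 matched interface C-alpha atoms")
    mu = unbound.coords[[keyed_u[k] for k in common]]
    mb = bound.coords[[keyed_b[k] for k in common]]
    return superpose(mu, mb).rmsd


def classify_difficulty(unbound_bound_irmsd: float) -> str:
    """RB / M / D difficulty class from the unbound-bound interface RMSD."""
    if unbound_bound_irmsd < 0:
        raise ValueError("IRMSD must be nonnegative")
    if unbound_bound_irmsd <= 1.35:
        return "RB"
    if unbound_bound_irmsd <= 2.5:
        return "M"
    return "D"
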