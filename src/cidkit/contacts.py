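"""Geometric protein–ligand interaction detection on PDB structures.

Detects four interaction kinds between a protein and bound
oligosaccharide ligands (and, for salt bridges and pi-cation pairs,
within the protein):

- hydrogen bonds: polar protein atom (N/O/S) within a donor–acceptor
  distance cutoff of a polar ligand atom (N/O); an explicit D-H...A
  angle filter is applied only when hydrogens are present in the model,
  since most crystal structures lack them.
- water-mediated hydrogen bonds: protein polar — water oxygen — ligand
  polar, both legs within a cutoff.
- hydrophobic contacts: carbon–carbon pairs closer than the sum of the
  van der Waals radii plus a tolerance.
- salt bridges: Asp/Glu carboxylate oxygen to Arg/Lys/His side-chain
  nitrogen.
- pi-cation: aromatic ring centroid (Tyr/Phe/Trp/His) to cationic group
  centroid (Arg guanidinium, Lys ammonium).

All cutoffs live in :class:`ContactCriteria` and default to conventional
structural-biology values; they are deliberately configurable because
published contact lists rarely state the geometric criteria used.
Contacts are attributed to sugar subsites (-n..+n along the binding
cleft) via user-supplied labels on the ligand residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

#: Hetero residue names treated as sugar ligands by default.
SUGAR_CODES = frozenset(
    {"NAG", "NDG", "BMA", "MAN", "GLC", "BGC", "GAL", "NAA", "ALI", "GCS"}
)
WATER = "HOH"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AROMATIC_RING_ATOMS = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
CATION_GROUP_ATOMS = {
    "ARG": ("CZ", "NE", "NH1", "NH2"),
    "LYS": ("NZ",),
}
ANIONIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
CATIONIC_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}


class StructureParseError(ValueError):
    """Raised when a PDB file cannot be parsed into atoms."""


class ContactConfigError(ValueError):
    """Raised for incomplete contact criteria (e.g. missing vdW radius)."""


class EmptySelectionError(ValueError):
    """Raised when a ligand selection matches no residues."""


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric cutoffs for interaction detection (all distances in Å)."""

    hbond_max_da: float = 3.5
    hbond_min_angle: float = 90.0  # applied only with explicit hydrogens
    vdw_radii: dict[str, float] = field(
        hash=False,
        default_factory=lambda: {
            "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
        },
    )
    hydrophobic_tolerance: float = 0.5
    salt_bridge_max: float = 4.0
    pi_cation_max: float = 6.0
    water_bridge_max: float = 3.5

    def __post_init__(self) -> None:
        for name in (
            "hbond_max_da", "hydrophobic_tolerance", "salt_bridge_max",
            "pi_cation_max", "water_bridge_max",
        ):
            if getattr(self, name) <= 0:
                raise ContactConfigError(f"{name} must be positive")


@dataclass
class StructureModel:
    """First model of a PDB structure as a biotite ``AtomArray``."""

    atoms: AtomArray
    source: Optional[str] = None

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coord

    def protein_mask(self) -> np.ndarray:
        return (~self.atoms.hetero) & (self.atoms.res_name != WATER)

    def water_mask(self) -> np.ndarray:
        return self.atoms.res_name == WATER

    def residue_key(self, i: int) -> tuple[str, int, str]:
        a = self.atoms
        return (str(a.chain_id[i]), int(a.res_id[i]), str(a.res_name[i]))

    def residue_label(self, i: int) -> str:
        """One-letter+number label like ``'R446'`` (3-letter if unknown)."""
        a = self.atoms
        one = THREE_TO_ONE.get(str(a.res_name[i]), str(a.res_name[i]))
        return f"{one}{int(a.res_id[i])}"


def parse_structure(path: str | Path) -> StructureModel:
    """Parse a PDB file: first model only, first/blank altloc kept."""
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(
            model=1, altloc="first", extra_fields=["occupancy"]
        )
    except Exception as exc:  # biotite raises various subclasses
        raise StructureParseError(f"{path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureParseError(f"{path}: no ATOM/HETATM records")
    if not np.all(np.isfinite(atoms.coord)):
        raise StructureParseError(f"{path}: non-finite coordinates")
    return StructureModel(atoms=atoms, source=str(path))


@dataclass(frozen=True)
class LigandSelection:
    """Ordered hetero residues treated as the ligand, with subsite labels.

    ``subsite_labels`` maps a residue key ``(chain, res_id, res_name)``
    to its signed subsite (e.g. -3..+3 along the binding cleft); missing
    entries are reported as unassigned.
    """

    residues: tuple[tuple[str, int, str], ...]
    subsite_labels: dict[tuple[str, int, str], int] = field(
        hash=False, default_factory=dict
    )

    def subsite(self, key: tuple[str, int, str]) -> Optional[int]:
        return self.subsite_labels.get(key)


def select_ligand(
    model: StructureModel,
    residue_names: frozenset[str] | set[str] = SUGAR_CODES,
    chain: Optional[str] = None,
    subsites: Optional[Sequence[int]] = None,
) -> LigandSelection:
    """Collect hetero residues with matching names, in sequence order.

    ``subsites``, if given, labels the selected residues in order (must
    match the selection length).
    """
    a = model.atoms
    mask = a.hetero & np.isin(a.res_name, list(residue_names))
    if chain is not None:
        mask &= a.chain_id == chain
    keys: list[tuple[str, int, str]] = []
    for i in np.flatnonzero(mask):
        key = model.residue_key(int(i))
        if key not in keys:
            keys.append(key)
    if not keys:
        raise EmptySelectionError(
            f"no hetero residues matching {sorted(residue_names)} found"
        )
    keys.sort(key=lambda k: (k[0], k[1]))
    labels: dict[tuple[str, int, str], int] = {}
    if subsites is not None:
        if len(subsites) != len(keys):
            raise ValueError(
                f"{len(subsites)} subsite labels for {len(keys)} ligand "
                f"residues"
            )
        labels = dict(zip(keys, (int(s) for s in subsites)))
    return LigandSelection(residues=tuple(keys), subsite_labels=labels)


@dataclass(frozen=True)
class ContactRecord:
    """One detected interaction.

    For pi-cation records the "atoms" are group centroids and the
    residue fields name the aromatic (protein side) and cationic
    (partner side) residues.
    """

    kind: str  # hbond | hydrophobic | salt_bridge | pi_cation
    protein_res: str
    protein_atom: str
    ligand_res: str
    ligand_atom: str
    distance: float
    subsite: Optional[int] = None
    water_mediated: bool = False
    water_res: Optional[str] = None
    angle: Optional[float] = None


def _ligand_atom_mask(
    model: StructureModel, ligand: LigandSelection
) -> np.ndarray:
    a = model.atoms
    mask = np.zeros(model.n_atoms, dtype=bool)
    keys = set(ligand.residues)
    for i in range(model.n_atoms):
        if a.hetero[i] and model.residue_key(i) in keys:
            mask[i] = True
    return mask


def _pairs_within(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float
) -> list[tuple[int, int, float]]:
    """Index pairs (into a, into b) with distance <= cutoff, via KD-trees."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return []
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    out = []
    for ia, neighbours in enumerate(
        tree_a.query_ball_tree(tree_b, cutoff)
    ):
        for ib in neighbours:
            d = float(np.linalg.norm(coords_a[ia] - coords_b[ib]))
            if d <= cutoff:
                out.append((ia, ib, d))
    return out


def _make_record(
    model: StructureModel,
    ligand: LigandSelection,
    kind: str,
    ip: int,
    il: int,
    dist: float,
    **extra,
) -> ContactRecord:
    a = model.atoms
    key = model.residue_key(il)
    return ContactRecord(
        kind=kind,
        protein_res=model.residue_label(ip),
        protein_atom=str(a.atom_name[ip]),
        ligand_res=f"{key[2]}{key[1]}",
        ligand_atom=str(a.atom_name[il]),
        distance=dist,
        subsite=ligand.subsite(key),
        **extra,
    )


def _hbond_angle_ok(
    model: StructureModel, ip: int, il: int, criteria: ContactCriteria
) -> tuple[bool, Optional[float]]:
    """D-H...A angle filter; permissive when no hydrogen is attached.

    Looks for hydrogens covalently close (<= 1.25 Å) to either partner;
    if any exists, the bond is kept when the best X-H...Y angle over
    those hydrogens reaches the criterion.
    """
    a = model.atoms
    h_idx = np.flatnonzero(a.element == "H")
    if len(h_idx) == 0:
        return True, None
    best: Optional[float] = None
    for donor, acceptor in ((ip, il), (il, ip)):
        d_xyz = a.coord[donor]
        h_near = h_idx[
            np.linalg.norm(a.coord[h_idx] - d_xyz, axis=1) <= 1.25
        ]
        for ih in h_near:
            hv = a.coord[ih]
            v1 = d_xyz - hv
            v2 = a.coord[acceptor] - hv
            cosang = np.dot(v1, v2) / (
                np.linalg.norm(v1) * np.linalg.norm(v2)
            )
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if best is None or ang > best:
                best = ang
    if best is None:
        return True, None
    return best >= criteria.hbond_min_angle, best


def find_hbonds(
    model: StructureModel,
    ligand: LigandSelection,
    criteria: ContactCriteria = ContactCriteria(),
) -> list[ContactRecord]:
    """Protein(N/O/S) — ligand(N/O) pairs within the donor–acceptor cutoff.

    Donor/acceptor typing is element-based and symmetric in orientation;
    without explicit hydrogens every polar–polar pair within the cutoff
    counts.
    """
    a = model.atoms
    prot = model.protein_mask() & np.isin(a.element, ["N", "O", "S"])
    lig = _ligand_atom_mask(model, ligand) & np.isin(a.element, ["N", "O"])
    ip_idx = np.flatnonzero(prot)
    il_idx = np.flatnonzero(lig)
    records = []
    for ia, ib, d in _pairs_within(
        a.coord[ip_idx], a.coord[il_idx], criteria.hbond_max_da
    ):
        ip, il = int(ip_idx[ia]), int(il_idx[ib])
        ok, ang = _hbond_angle_ok(model, ip, il, criteria)
        if ok:
            records.append(
                _make_record(model, ligand, "hbond", ip, il, d, angle=ang)
            )
    records.sort(key=lambda r: (r.ligand_res, r.protein_res, r.distance))
    return records


def find_water_mediated_hbonds(
    model: StructureModel,
    ligand: LigandSelection,
    criteria: ContactCriteria = ContactCriteria(),
) -> list[ContactRecord]:
    """Protein polar — water O — ligand polar bridges, both legs in cutoff.

    The recorded distance is the longer of the two legs.
    """
    a = model.atoms
    prot = model.protein_mask() & np.isin(a.element, ["N", "O", "S"])
    lig = _ligand_atom_mask(model, ligand) & np.isin(a.element, ["N", "O"])
    wat = model.water_mask() & (a.element == "O")
    ip_idx = np.flatnonzero(prot)
    il_idx = np.flatnonzero(lig)
    iw_idx = np.flatnonzero(wat)
    records = []
    cut = criteria.water_bridge_max
    for iw in iw_idx:
        w_xyz = a.coord[iw]
        d_prot = np.linalg.norm(a.coord[ip_idx] - w_xyz, axis=1)
        d_lig = np.linalg.norm(a.coord[il_idx] - w_xyz, axis=1)
        near_p = ip_idx[d_prot <= cut]
        near_l = il_idx[d_lig <= cut]
        for ip in near_p:
            dp = float(np.linalg.norm(a.coord[ip] - w_xyz))
            for il in near_l:
                dl = float(np.linalg.norm(a.coord[il] - w_xyz))
                wkey = model.residue_key(int(iw))
                records.append(
                    _make_record(
                        model, ligand, "hbond", int(ip), int(il),
                        max(dp, dl), water_mediated=True,
                        water_res=f"{wkey[2]}{wkey[1]}",
                    )
                )
    records.sort(key=lambda r: (r.ligand_res, r.protein_res, r.distance))
    return records


def find_hydrophobic_contacts(
    model: StructureModel,
    ligand: LigandSelection,
    criteria: ContactCriteria = ContactCriteria(),
) -> list[ContactRecord]:
    """Protein C — ligand C pairs within vdW-radius sum plus tolerance."""
    a = model.atoms
    for element in np.unique(a.element[_ligand_atom_mask(model, ligand)]):
        if element not in criteria.vdw_radii and element in ("C",):
            raise ContactConfigError(f"no vdW radius for element {element}")
    if "C" not in criteria.vdw_radii:
        raise ContactConfigError("no vdW radius for element C")
    cutoff = 2 * criteria.vdw_radii["C"] + criteria.hydrophobic_tolerance
    prot = model.protein_mask() & (a.element == "C")
    lig = _ligand_atom_mask(model, ligand) & (a.element == "C")
    ip_idx = np.flatnonzero(prot)
    il_idx = np.flatnonzero(lig)
    records = [
        _make_record(
            model, ligand, "hydrophobic", int(ip_idx[ia]), int(il_idx[ib]), d
        )
        for ia, ib, d in _pairs_within(
            a.coord[ip_idx], a.coord[il_idx], cutoff
        )
    ]
    records.sort(key=lambda r: (r.ligand_res, r.protein_res, r.distance))
    return records


def _residue_atoms(
    model: StructureModel, res_name_to_atoms: dict[str, tuple[str, ...]]
) -> list[tuple[int, np.ndarray, list[int]]]:
    """Group centroids: (first atom index, centroid, atom indices)."""
    a = model.atoms
    groups: dict[tuple[str, int, str], list[int]] = {}
    for i in np.flatnonzero(model.protein_mask()):
        rn = str(a.res_name[i])
        if rn in res_name_to_atoms and str(a.atom_name[i]) in res_name_to_atoms[rn]:
            groups.setdefault(model.residue_key(int(i)), []).append(int(i))
    out = []
    for key, idx in groups.items():
        wanted = len(res_name_to_atoms[key[2]])
        if len(idx) >= min(3, wanted):  # tolerate partially modelled groups
            out.append((idx[0], a.coord[idx].mean(axis=0), idx))
    return out


def find_pi_cation(
    model: StructureModel, criteria: ContactCriteria = ContactCriteria()
) -> list[ContactRecord]:
    """Aromatic ring centroid — cationic group centroid pairs in cutoff.

    Protein-internal: e.g. the Tyr/Arg pair of the YxR motif.
    """
    rings = _residue_atoms(model, AROMATIC_RING_ATOMS)
    cations = _residue_atoms(model, CATION_GROUP_ATOMS)
    records = []
    for ri, r_cent, _ in rings:
        for ci, c_cent, _ in cations:
            if model.residue_key(ri) == model.residue_key(ci):
                continue
            d = float(np.linalg.norm(r_cent - c_cent))
            if d <= criteria.pi_cation_max:
                records.append(
                    ContactRecord(
                        kind="pi_cation",
                        protein_res=model.residue_label(ri),
                        protein_atom="ring_centroid",
                        ligand_res=model.residue_label(ci),
                        ligand_atom="cation_centroid",
                        distance=d,
                    )
                )
    records.sort(key=lambda r: (r.protein_res, r.ligand_res, r.distance))
    return records


def find_salt_bridges(
    model: StructureModel, criteria: ContactCriteria = ContactCriteria()
) -> list[ContactRecord]:
    """Asp/Glu carboxylate O — Arg/Lys/His side-chain N pairs in cutoff."""
    a = model.atoms
    prot_idx = np.flatnonzero(model.protein_mask())
    anions = [
        int(i) for i in prot_idx
        if str(a.res_name[i]) in ANIONIC_ATOMS
        and str(a.atom_name[i]) in ANIONIC_ATOMS[str(a.res_name[i])]
    ]
    cations = [
        int(i) for i in prot_idx
        if str(a.res_name[i]) in CATIONIC_ATOMS
        and str(a.atom_name[i]) in CATIONIC_ATOMS[str(a.res_name[i])]
    ]
    records = []
    for ia in anions:
        for ic in cations:
            d = float(np.linalg.norm(a.coord[ia] - a.coord[ic]))
            if d <= criteria.salt_bridge_max:
                records.append(
                    ContactRecord(
                        kind="salt_bridge",
                        protein_res=model.residue_label(ia),
                        protein_atom=str(a.atom_name[ia]),
                        ligand_res=model.residue_label(ic),
                        ligand_atom=str(a.atom_name[ic]),
                        distance=d,
                    )
                )
    records.sort(key=lambda r: (r.protein_res, r.ligand_res, r.distance))
    return records


def contact_table(
    model: StructureModel,
    ligand: LigandSelection,
    residue_groups: dict[str, str],
    criteria: ContactCriteria = ContactCriteria(),
    *,
    include_water_mediated: bool = True,
) -> pd.DataFrame:
    """Per-subsite summary of hbond and hydrophobic contact residues.

    ``residue_groups`` tags residue labels (e.g. ``'R446'``) with a group
    such as ``'CID'`` or ``'TIM barrel'``; untagged residues fall into
    group ``'other'``.  Rows are subsites, columns are
    ``(group, interaction kind)`` with comma-joined residue labels.
    """
    contacts = find_hbonds(model, ligand, criteria) + find_hydrophobic_contacts(
        model, ligand, criteria
    )
    if include_water_mediated:
        contacts += find_water_mediated_hbonds(model, ligand, criteria)
    cells: dict[tuple[object, str, str], set[str]] = {}
    for rec in contacts:
        group = residue_groups.get(rec.protein_res, "other")
        sub = rec.subsite if rec.subsite is not None else "unassigned"
        cells.setdefault((sub, group, rec.kind), set()).add(rec.protein_res)
    subsites = sorted(
        {k[0] for k in cells}, key=lambda s: (isinstance(s, str), s)
    )
    groups = sorted({k[1] for k in cells})
    rows = []
    for sub in subsites:
        row: dict[str, object] = {"subsite": sub}
        for group in groups:
            for kind in ("hbond", "hydrophobic"):
                residues = sorted(cells.get((sub, group, kind), set()))
                row[f"{group}_{kind}"] = ",".join(residues)
        rows.append(row)
    return pd.DataFrame(rows)


def contacts_to_tsv(records: Sequence[ContactRecord]) -> str:
    """Flat TSV contact report."""
    cols = [
        "kind", "protein_res", "protein_atom", "ligand_res", "ligand_atom",
        "distance", "subsite", "water_mediated",
    ]
    lines = ["\t".join(cols)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.kind, r.protein_res, r.protein_atom, r.ligand_res,
                    r.ligand_atom, f"{r.distance:.6g}",
                    "unassigned" if r.subsite is None else str(r.subsite),
                    str(r.water_mediated).lower(),
                ]
            )
        )
    return "\n".join(lines) + "\n"
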