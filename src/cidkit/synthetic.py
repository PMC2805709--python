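"""Generators for alignments, complexes and tree-evolved sequences.

Every pipeline stage in this package can be exercised on synthetic inputs
with known ground truth and no downloads:

- :func:`gen_alignment` realises alignment columns with exact residue
  compositions and gap counts, returning per-column truth labels derived
  from the specification (not from the generated data).
- :func:`twin_alignment` builds a 27-sequence synthetic twin of a
  CID-style alignment with a planted 9/5/5/2/5/6 breakdown of
  hydrophobic/hydrophilic/neutral × high/moderate conserved columns
  (32 conserved positions in total) plus low-conservation filler and
  gap-zeroed columns.
- :func:`gen_complex` writes a legal PDB-format protein–oligosaccharide
  complex with planted hydrogen bonds, hydrophobic contacts, a salt
  bridge, a pi-cation pair, an optional water bridge, and decoy atoms
  placed well outside every cutoff.  Sugar rings are simplified NAG
  rings (heavy ring atoms plus one exocyclic oxygen).
- :func:`evolve_on_tree` evolves ungapped protein sequences down a tree
  under a uniform-rate 20-state substitution model.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile
from skbio import TreeNode

from cidkit.alignment import (
    AMINO_ACIDS,
    GAP,
    AlignedRecord,
    AlignedSequenceSet,
)
from cidkit.profiles import (
    ColumnProfile,
    ProfileConfig,
    apply_gap_rule,
    bin_conservation,
    classify_position,
    column_hydropathy,
    conservation_score,
    shannon_entropy,
)
from cidkit.profiles import ConservationRecord


class SpecError(ValueError):
    """Raised for inconsistent generator specifications."""


# ---------------------------------------------------------------------------
# Alignment generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnSpec:
    """One column: exact residue counts (or probabilities) plus gaps.

    Integer values are exact counts; float values are sampling
    probabilities (must sum to 1) applied i.i.d. over the non-gap rows.
    """

    composition: dict[str, int | float] = field(hash=False)
    gap_count: int = 0


@dataclass(frozen=True)
class AlignmentSpec:
    n_seqs: int
    columns: tuple[ColumnSpec, ...]
    seed: int = 0


@dataclass(frozen=True)
class ColumnTruth:
    """Intended conservation bin and physicochemical class of a column."""

    column: int
    bin: str
    phys_class: str


def _column_truth(
    col: int, counts: dict[str, int], gap_count: int, cfg: ProfileConfig
) -> ColumnTruth:
    """Truth labels computed from the *spec* composition."""
    prof = ColumnProfile(column=col, counts=dict(counts), gap_count=gap_count)
    if prof.n_obs == 0:
        return ColumnTruth(column=col, bin="gap_zeroed", phys_class="unclassified")
    m = (
        max(2, prof.n_types)
        if cfg.entropy_m == "observed"
        else int(cfg.entropy_m)
    )
    S = shannon_entropy(prof)
    C = conservation_score(S, m)
    rec = ConservationRecord(
        column=col, entropy=S, score=C, m=m,
        bin=bin_conservation(C, high_cut=cfg.high_cut, moderate_cut=cfg.moderate_cut),
    )
    rec = apply_gap_rule(rec, gap_count)
    if rec.bin not in ("high", "moderate"):
        return ColumnTruth(column=col, bin=rec.bin, phys_class="unclassified")
    hyd = column_hydropathy(prof, cfg.scale)
    return ColumnTruth(
        column=col, bin=rec.bin,
        phys_class=classify_position(rec, hyd, prof, cfg),
    )


def gen_alignment(
    spec: AlignmentSpec, cfg: ProfileConfig = ProfileConfig()
) -> tuple[AlignedSequenceSet, list[ColumnTruth]]:
    """Realise an alignment column by column, with ground-truth labels.

    Exact-count compositions are realised exactly (the residues are
    shuffled across rows so conservation statistics, which are
    row-permutation invariant, are unaffected).  Sequence ids are
    ``S01..SN``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_seqs
    if n < 1:
        raise SpecError("n_seqs must be >= 1")
    columns: list[list[str]] = []
    truths: list[ColumnTruth] = []
    for ci, cspec in enumerate(spec.columns, start=1):
        for res in cspec.composition:
            if res not in AMINO_ACIDS:
                raise SpecError(f"column {ci}: unknown residue {res!r}")
        if cspec.gap_count < 0 or cspec.gap_count > n:
            raise SpecError(f"column {ci}: gap_count {cspec.gap_count} invalid")
        n_obs = n - cspec.gap_count
        values = list(cspec.composition.values())
        if all(isinstance(v, int) or float(v).is_integer() for v in values):
            counts = {r: int(v) for r, v in cspec.composition.items()}
            if sum(counts.values()) != n_obs:
                raise SpecError(
                    f"column {ci}: counts sum to {sum(counts.values())}, "
                    f"expected {n_obs} (N={n}, gaps={cspec.gap_count})"
                )
        else:
            probs = {r: float(v) for r, v in cspec.composition.items()}
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise SpecError(f"column {ci}: probabilities must sum to 1")
            drawn = rng.multinomial(n_obs, list(probs.values()))
            counts = {
                r: int(c) for r, c in zip(probs, drawn)
            }
        letters = [r for r, c in counts.items() for _ in range(c)]
        letters += [GAP] * cspec.gap_count
        rng.shuffle(letters)
        columns.append(letters)
        truths.append(_column_truth(ci, counts, cspec.gap_count, cfg))
    width = max(2, len(str(n)))
    records = tuple(
        AlignedRecord(
            seq_id=f"S{row + 1:0{width}d}",
            residues="".join(col[row] for col in columns),
        )
        for row in range(n)
    )
    return AlignedSequenceSet(records=records), truths


# -- the synthetic twin of a CID-style alignment ----------------------------

#: Planted class breakdown of the synthetic twin: 32 conserved positions.
TWIN_CLASS_COUNTS: dict[tuple[str, str], int] = {
    ("high", "hydrophobic"): 9,
    ("moderate", "hydrophobic"): 5,
    ("high", "hydrophilic"): 5,
    ("moderate", "hydrophilic"): 2,
    ("high", "neutral"): 5,
    ("moderate", "neutral"): 6,
}

_HB_MODERATE = {"I": 5, "L": 5, "F": 5, "W": 4, "Y": 4, "M": 4}
_HP_MODERATE = {"D": 5, "E": 5, "K": 5, "N": 4, "Q": 4, "S": 4}
_NEUTRAL_MODERATE = {"G": 6, "A": 6, "P": 5, "S": 4, "T": 3, "N": 3}
_LOW_FILLER = {r: 3 for r in "ACDEFGHIK"}  # 9 types uniform: low conservation


def twin_alignment(
    seed: int = 0, n_filler: int = 8, n_gap_columns: int = 4
) -> tuple[AlignedSequenceSet, list[ColumnTruth]]:
    """27-sequence alignment with the planted 9/5/5/2/5/6 class breakdown.

    Emulates the statistical structure of a CID alignment: a mix of
    invariant and moderately conserved columns of each physicochemical
    class, low-conservation filler, and a few columns zeroed by the
    more-than-one-gap rule.  Column order is shuffled deterministically
    by the seed.
    """
    n = 27
    cols: list[ColumnSpec] = []
    for res in ["I", "L", "F", "W", "Y", "I", "L", "F", "W"]:  # 9 hb-high
        cols.append(ColumnSpec(composition={res: n}))
    cols += [ColumnSpec(composition=dict(_HB_MODERATE))] * 5
    for res in ["D", "E", "K", "N", "S"]:  # 5 hydrophilic-high
        cols.append(ColumnSpec(composition={res: n}))
    cols += [ColumnSpec(composition=dict(_HP_MODERATE))] * 2
    for res in ["G", "A", "P", "G", "A"]:  # 5 neutral-high
        cols.append(ColumnSpec(composition={res: n}))
    cols += [ColumnSpec(composition=dict(_NEUTRAL_MODERATE))] * 6
    cols += [ColumnSpec(composition=dict(_LOW_FILLER))] * n_filler
    cols += [
        ColumnSpec(composition={"Y": n - 2}, gap_count=2)
    ] * n_gap_columns
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cols))
    spec = AlignmentSpec(
        n_seqs=n, columns=tuple(cols[i] for i in order), seed=seed
    )
    return gen_alignment(spec)


def motif_alignment(
    seed: int = 0,
    n_seqs: int = 12,
    yxr_anchor: int = 10,
    edxxvi_anchor: int = 20,
    length: int = 30,
) -> AlignedSequenceSet:
    """Alignment with YxR and [E/D]xx[V/I] planted at known anchors.

    Motif slot columns are invariant (occupancy 1.0); every other column
    is filled with a high-entropy 9-type composition so that no other
    column is conserved and no spurious anchor can fire.
    """
    planted = {
        yxr_anchor: "Y", yxr_anchor + 2: "R",
        edxxvi_anchor: "E", edxxvi_anchor + 3: "I",
    }
    if max(planted) > length:
        raise SpecError("planted motif extends past alignment end")
    cols = []
    for col in range(1, length + 1):
        if col in planted:
            cols.append(ColumnSpec(composition={planted[col]: n_seqs}))
        else:
            base, extra = divmod(n_seqs, 9)
            comp = {
                r: base + (1 if i < extra else 0)
                for i, r in enumerate("ACDEFGHIK")
            }
            comp = {r: c for r, c in comp.items() if c > 0}
            cols.append(ColumnSpec(composition=comp))
    aln, _ = gen_alignment(
        AlignmentSpec(n_seqs=n_seqs, columns=tuple(cols), seed=seed)
    )
    return aln


# ---------------------------------------------------------------------------
# Complex generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexSpec:
    """Planted-contact geometry for a synthetic protein–sugar complex.

    Distances are in Å and must lie inside the default detection
    criteria; decoy atoms are placed more than 20 Å from everything.
    """

    n_sugars: int = 3
    n_hbonds: int = 2
    hbond_distance: float = 2.9
    n_hydrophobic: int = 1
    cc_distance: float = 3.7
    salt_bridge: bool = True
    salt_bridge_distance: float = 3.2
    pi_cation: bool = True
    pi_cation_distance: float = 4.5
    water_bridge: bool = False
    water_bridge_distance: float = 2.8
    n_decoys: int = 0
    subsites: Optional[tuple[int, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sugars < 1:
            raise SpecError("need at least one sugar residue")
        if self.n_hbonds > self.n_sugars:
            raise SpecError("more planted hbonds than sugar residues")
        if self.n_hydrophobic > self.n_sugars:
            raise SpecError("more planted CC contacts than sugar residues")
        if self.water_bridge and self.n_hbonds >= self.n_sugars:
            raise SpecError(
                "water bridge needs a sugar without a direct hbond"
            )
        for name, val, limit in (
            ("hbond_distance", self.hbond_distance, 3.5),
            ("cc_distance", self.cc_distance, 3.9),
            ("salt_bridge_distance", self.salt_bridge_distance, 4.0),
            ("pi_cation_distance", self.pi_cation_distance, 6.0),
            ("water_bridge_distance", self.water_bridge_distance, 3.5),
        ):
            if not 1.5 <= val <= limit:
                raise SpecError(
                    f"{name}={val} outside plantable range [1.5, {limit}]"
                )


@dataclass(frozen=True)
class PlantedContact:
    kind: str
    protein_res: str
    protein_atom: str
    ligand_res: str
    ligand_atom: str
    distance: float
    water_mediated: bool = False


@dataclass
class SyntheticComplex:
    atoms: AtomArray
    truth: list[PlantedContact]
    subsites: Optional[tuple[int, ...]]

    def write(self, path: str | Path) -> None:
        pdb = PDBFile()
        pdb.set_structure(self.atoms)
        pdb.write(str(path))


_RING_NAMES = ("C1", "C2", "C3", "C4", "C5", "O5")


def _ring_coords(center: np.ndarray, radius: float = 1.42) -> dict[str, np.ndarray]:
    """Simplified pyranose ring: hexagon in the xz-plane plus O3 on C3."""
    out = {}
    for m, name in enumerate(_RING_NAMES):
        ang = math.radians(60 * m)
        out[name] = center + radius * np.array(
            [math.cos(ang), 0.0, math.sin(ang)]
        )
    out["O3"] = out["C3"] + np.array([0.0, 1.4, 0.0])
    return out


class _Builder:
    def __init__(self) -> None:
        self.rows: list[tuple[str, int, str, str, str, bool, np.ndarray]] = []

    def add(self, chain: str, res_id: int, res_name: str, atom: str,
            element: str, hetero: bool, xyz: np.ndarray) -> None:
        self.rows.append((chain, res_id, res_name, atom, element, hetero,
                          np.asarray(xyz, dtype=float)))

    def build(self) -> AtomArray:
        arr = AtomArray(len(self.rows))
        for i, (chain, rid, rname, atom, element, het, xyz) in enumerate(
            self.rows
        ):
            arr.chain_id[i] = chain
            arr.res_id[i] = rid
            arr.res_name[i] = rname
            arr.atom_name[i] = atom
            arr.element[i] = element
            arr.hetero[i] = het
            arr.coord[i] = xyz
        return arr


def gen_complex(spec: ComplexSpec) -> SyntheticComplex:
    """Build a synthetic holo complex realising the planted contacts.

    Layout: NAG rings along +x at 7 Å spacing; interacting protein
    residues approach from +y; the salt-bridge and pi-cation pairs sit
    far on -x; decoys far on -y.  The construction is validated with a
    brute-force all-pairs distance scan and a :class:`SpecError` is
    raised if the geometry produces any contact beyond the planted set.
    """
    b = _Builder()
    truth: list[PlantedContact] = []
    rings = []
    for k in range(spec.n_sugars):
        center = np.array([7.0 * k, 0.0, 0.0])
        coords = _ring_coords(center)
        rings.append(coords)
        for name in (*_RING_NAMES, "O3"):
            b.add("L", k + 1, "NAG", name, name[0], True, coords[name])

    # direct hydrogen bonds: Ser OG above O3 of sugars 1..n_hbonds
    up = np.array([0.0, 1.0, 0.0])
    for k in range(spec.n_hbonds):
        og = rings[k]["O3"] + spec.hbond_distance * up
        rid = 101 + k
        b.add("A", rid, "SER", "OG", "O", False, og)
        b.add("A", rid, "SER", "CB", "C", False, og + 1.4 * up)
        b.add("A", rid, "SER", "CA", "C", False, og + 2.8 * up)
        truth.append(
            PlantedContact(
                "hbond", f"S{rid}", "OG", f"NAG{k + 1}", "O3",
                spec.hbond_distance,
            )
        )

    # hydrophobic contacts: Ala CB above C1 of sugars counted from the end
    for k in range(spec.n_hydrophobic):
        sugar = spec.n_sugars - 1 - k
        cb = rings[sugar]["C1"] + spec.cc_distance * up
        rid = 201 + k
        b.add("A", rid, "ALA", "CB", "C", False, cb)
        b.add("A", rid, "ALA", "CA", "C", False, cb + 1.5 * up)
        truth.append(
            PlantedContact(
                "hydrophobic", f"A{rid}", "CB", f"NAG{sugar + 1}", "C1",
                spec.cc_distance,
            )
        )

    # water bridge on the last sugar without a direct hbond
    if spec.water_bridge:
        sugar = spec.n_hbonds  # first sugar with no direct hbond
        d = spec.water_bridge_distance
        o3 = rings[sugar]["O3"]
        water = o3 + d * up
        og = water + d * up
        b.add("A", 150, "SER", "OG", "O", False, og)
        b.add("A", 150, "SER", "CB", "C", False, og + 1.4 * up)
        b.add("W", 501, "HOH", "O", "O", True, water)
        truth.append(
            PlantedContact(
                "hbond", "S150", "OG", f"NAG{sugar + 1}", "O3", d,
                water_mediated=True,
            )
        )

    # salt bridge, far from the ligand on -x
    if spec.salt_bridge:
        od1 = np.array([-15.0, 5.0, 0.0])
        nh1 = od1 + spec.salt_bridge_distance * up
        b.add("A", 301, "ASP", "OD1", "O", False, od1)
        b.add("A", 301, "ASP", "OD2", "O", False, od1 + np.array([0.0, -1.2, 1.2]))
        b.add("A", 301, "ASP", "CG", "C", False, od1 + np.array([0.0, -1.2, -0.6]))
        b.add("A", 302, "ARG", "NH1", "N", False, nh1)
        b.add("A", 302, "ARG", "CZ", "C", False, nh1 + np.array([0.0, 1.3, 0.0]))
        b.add("A", 302, "ARG", "NH2", "N", False, nh1 + np.array([1.2, 1.9, 0.0]))
        b.add("A", 302, "ARG", "NE", "N", False, nh1 + np.array([-1.2, 1.9, 0.0]))
        truth.append(
            PlantedContact(
                "salt_bridge", "D301", "OD1", "R302", "NH1",
                spec.salt_bridge_distance,
            )
        )

    # pi-cation pair, further out on -x
    if spec.pi_cation:
        ring_center = np.array([-30.0, 5.0, 0.0])
        for m, name in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2")):
            ang = math.radians(60 * m)
            b.add(
                "A", 401, "TYR", name, "C", False,
                ring_center + 1.39 * np.array([math.cos(ang), 0.0, math.sin(ang)]),
            )
        b.add("A", 401, "TYR", "CB", "C", False,
              ring_center + np.array([0.0, -2.2, 0.0]))
        c = ring_center + spec.pi_cation_distance * up
        # offsets averaging to zero keep the group centroid exactly at c
        b.add("A", 402, "ARG", "CZ", "C", False, c + np.array([0.0, -0.65, 0.0]))
        b.add("A", 402, "ARG", "NE", "N", False, c + np.array([-1.15, 0.25, 0.0]))
        b.add("A", 402, "ARG", "NH1", "N", False, c + np.array([1.15, 0.25, 0.0]))
        b.add("A", 402, "ARG", "NH2", "N", False, c + np.array([0.0, 0.15, 0.0]))
        truth.append(
            PlantedContact(
                "pi_cation", "Y401", "ring_centroid", "R402",
                "cation_centroid", spec.pi_cation_distance,
            )
        )

    # decoys: single carbon/oxygen atoms far from everything
    rng = np.random.default_rng(spec.seed)
    for k in range(spec.n_decoys):
        pos = np.array([4.0 * k - 30.0, -25.0 - rng.uniform(0, 3), 10.0])
        if k % 2 == 0:
            b.add("A", 901 + k, "GLY", "CA", "C", False, pos)
        else:
            b.add("W", 901 + k, "HOH", "O", "O", True, pos)

    atoms = b.build()
    _validate_complex(atoms, truth, spec)
    return SyntheticComplex(atoms=atoms, truth=truth, subsites=spec.subsites)


def _validate_complex(
    atoms: AtomArray, truth: list[PlantedContact], spec: ComplexSpec
) -> None:
    """Brute-force all-pairs scan: planted contacts and nothing else."""
    def label(i: int) -> tuple[str, str]:
        one = {"SER": "S", "ALA": "A", "ASP": "D", "ARG": "R", "GLY": "G",
               "TYR": "Y", "NAG": "NAG", "HOH": "HOH"}[str(atoms.res_name[i])]
        prefix = one if one in ("NAG", "HOH") else one
        return (f"{prefix}{int(atoms.res_id[i])}", str(atoms.atom_name[i]))

    n = atoms.array_length()
    coord = atoms.coord
    dist = np.linalg.norm(coord[:, None, :] - coord[None, :, :], axis=-1)
    prot = (~atoms.hetero) & (atoms.res_name != "HOH")
    lig = atoms.hetero & (atoms.res_name == "NAG")
    wat = atoms.res_name == "HOH"
    polar = np.isin(atoms.element, ["N", "O", "S"])
    carbon = atoms.element == "C"

    found: set[tuple] = set()
    for i in range(n):
        for j in range(n):
            if prot[i] and lig[j]:
                if polar[i] and atoms.element[j] in ("N", "O") and dist[i, j] <= 3.5:
                    found.add(("hbond", *label(i), *label(j)))
                if carbon[i] and carbon[j] and dist[i, j] <= 3.9:
                    found.add(("hydrophobic", *label(i), *label(j)))
    # water bridges
    for w in np.flatnonzero(wat & (atoms.element == "O")):
        near_p = [i for i in np.flatnonzero(prot & polar) if dist[w, i] <= 3.5]
        near_l = [
            j for j in np.flatnonzero(lig & np.isin(atoms.element, ["N", "O"]))
            if dist[w, j] <= 3.5
        ]
        for i in near_p:
            for j in near_l:
                found.add(("water_hbond", *label(i), *label(j)))
    # salt bridges
    for i in range(n):
        rn_i, an_i = str(atoms.res_name[i]), str(atoms.atom_name[i])
        if rn_i in ("ASP", "GLU") and an_i in ("OD1", "OD2", "OE1", "OE2"):
            for j in range(n):
                rn_j, an_j = str(atoms.res_name[j]), str(atoms.atom_name[j])
                if (
                    (rn_j == "ARG" and an_j in ("NE", "NH1", "NH2"))
                    or (rn_j == "LYS" and an_j == "NZ")
                ) and dist[i, j] <= 4.0:
                    found.add(("salt_bridge", *label(i), *label(j)))

    # pi-cation: ring centroid vs cation-group centroid count
    ring_centroids = {}
    cation_centroids = {}
    for i in range(n):
        rn, an = str(atoms.res_name[i]), str(atoms.atom_name[i])
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]))
        if rn in ("TYR", "PHE", "TRP", "HIS") and an in (
            "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "NE1", "ND1", "NE2",
            "CE3", "CZ2", "CZ3", "CH2",
        ):
            ring_centroids.setdefault(key, []).append(coord[i])
        if (rn == "ARG" and an in ("CZ", "NE", "NH1", "NH2")) or (
            rn == "LYS" and an == "NZ"
        ):
            cation_centroids.setdefault(key, []).append(coord[i])
    n_pi = sum(
        1
        for rc in ring_centroids.values()
        for cc in cation_centroids.values()
        if np.linalg.norm(
            np.mean(rc, axis=0) - np.mean(cc, axis=0)
        ) <= 6.0
    )
    n_pi_expected = sum(1 for t in truth if t.kind == "pi_cation")
    if n_pi != n_pi_expected:
        raise SpecError(
            f"infeasible complex geometry: {n_pi} pi-cation pairs found, "
            f"{n_pi_expected} planted"
        )

    expected: set[tuple] = set()
    for t in truth:
        kind = "water_hbond" if t.water_mediated else t.kind
        if t.kind == "pi_cation":
            continue  # centroid-based; checked above
        expected.add(
            (kind, t.protein_res, t.protein_atom, t.ligand_res, t.ligand_atom)
        )
    if found != expected:
        raise SpecError(
            "infeasible complex geometry: brute-force scan found "
            f"{sorted(found - expected)} beyond / {sorted(expected - found)} "
            "missing from the planted set"
        )


def random_rigid_transform(
    atoms: AtomArray, seed: int = 0
) -> AtomArray:
    """Apply a random rotation + translation to a copy of the structure."""
    rng = np.random.default_rng(seed)
    # random rotation via QR decomposition of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.uniform(-50, 50, size=3)
    out = atoms.copy()
    out.coord = atoms.coord @ q.T + shift
    return out


# ---------------------------------------------------------------------------
# Sequence evolution on a tree
# ---------------------------------------------------------------------------

def substitution_probability(branch_length: float) -> float:
    """P(site differs from parent) after a branch, uniform-rate 20-state model.

    With substitutions at rate 1 per unit branch length and the new
    residue uniform over the other 19 types, the probability that a site
    ends in a different state than it started is
    ``(19/20) * (1 - exp(-20 b / 19))``, saturating at 19/20.
    """
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    return (19.0 / 20.0) * (1.0 - math.exp(-20.0 * branch_length / 19.0))


def evolve_on_tree(
    tree: TreeNode, sequence_length: int, seed: int = 0
) -> AlignedSequenceSet:
    """Evolve ungapped sequences down a tree with branch lengths.

    The root sequence is drawn uniformly over the 20 amino acids; along
    each branch every site substitutes independently with the
    probability given by :func:`substitution_probability`, the new
    residue uniform over the other 19.  Leaves are returned in the
    tree's tip order.  Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    root_seq = rng.integers(0, 20, size=sequence_length)
    leaves: list[tuple[str, np.ndarray]] = []

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            b = child.length if child.length is not None else 0.0
            p = substitution_probability(b)
            child_seq = seq.copy()
            mutate = rng.random(sequence_length) < p
            n_mut = int(mutate.sum())
            if n_mut:
                # uniform over the other 19 types
                shift = rng.integers(1, 20, size=n_mut)
                child_seq[mutate] = (child_seq[mutate] + shift) % 20
            if child.is_tip():
                leaves.append((str(child.name), child_seq))
            else:
                descend(child, child_seq)

    if tree.is_tip():
        leaves.append((str(tree.name), root_seq))
    else:
        descend(tree, root_seq)
    records = tuple(
        AlignedRecord(
            seq_id=name,
            residues=alphabet[seq].tobytes().decode(),
        )
        for name, seq in leaves
    )
    return AlignedSequenceSet(records=records)
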