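"""Per-column conservation and hydropathy profiling of a protein alignment.

Conservation of column *i* is scored from the Shannon entropy of its
amino-acid composition,

    S(i) = - sum_j P_j(i) ln P_j(i),        C(i) = 1 - S(i) / ln(m),

where ``P_j(i)`` is the fractional occurrence of amino-acid type *j* among
the non-gap residues of the column and *m* is the number of amino-acid
types considered (20 by default).  ``C(i)`` is 1 for an invariant column
and 0 for a column uniform over all *m* types.  Columns are binned as
highly conserved (``C >= 0.45``), moderately conserved
(``0.35 <= C < 0.45``) or less conserved (``C < 0.35``); columns with more
than one gap are treated as non-conserved and forced to score 0.

Hydropathy of a column is the sum over residues of their side-chain
transfer free energies on the Nozaki–Tanford scale (kcal/mol), reported
both as the raw sum and as the per-residue mean.  Conserved columns are
classified as neutral (mostly Gly/Ala/Pro), hydrophobic or hydrophilic.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from cidkit.alignment import AMINO_ACIDS, GAP, AlignedSequenceSet

Bin = Literal["high", "moderate", "low", "gap_zeroed"]
PhysClass = Literal["hydrophobic", "hydrophilic", "neutral", "unclassified"]


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named per-residue hydrophobicity table (transfer free energies)."""

    name: str
    values: dict[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(
                f"scale {self.name!r} missing residues {sorted(missing)}"
            )

    @property
    def midpoint(self) -> float:
        vals = [self.values[a] for a in AMINO_ACIDS]
        return (min(vals) + max(vals)) / 2.0


#: Nozaki & Tanford (1971) side-chain transfer free energies, kcal/mol,
#: from water to ethanol/dioxane, in the widely used digitised form where
#: residues without a measured value are assigned 0.  Higher = more
#: hydrophobic; the scale spans 0 (Gly and polar residues) to 3.4 (Trp).
NOZAKI_TANFORD = HydrophobicityScale(
    name="nozaki-tanford",
    values={
        "A": 0.5, "R": 0.0, "N": 0.0, "D": 0.0, "C": 0.0,
        "Q": 0.0, "E": 0.0, "G": 0.0, "H": 0.5, "I": 1.8,
        "L": 1.8, "K": 0.0, "M": 1.3, "F": 2.5, "P": 1.4,
        "S": 0.0, "T": 0.4, "W": 3.4, "Y": 2.3, "V": 1.5,
    },
)

NEUTRAL_RESIDUES = frozenset("GAP")


@dataclass(frozen=True)
class ProfileConfig:
    """Thresholds and options for :func:`profile_alignment`.

    entropy_m
        Number of amino-acid types *m* in ``C(i) = 1 - S(i)/ln(m)``:
        the integer 20 (full alphabet, default) or the string
        ``"observed"`` to use the number of types seen in each column.
    high_cut, moderate_cut
        Conservation bin edges; ``C >= high_cut`` is high,
        ``moderate_cut <= C < high_cut`` moderate, below that low.
    neutral_majority
        Minimum combined fraction of Gly/Ala/Pro for a conserved column
        to be called neutral.
    hydrophobic_cut, hydrophilic_cut
        Thresholds on the mean hydropathy; ``None`` (default) places a
        single threshold at the scale's midpoint, so every non-neutral
        conserved column is classified.
    classify_by
        ``"hydropathy"`` (numeric mean, default) or ``"majority"``
        (most common residue's individual hydrophobicity decides).
    """

    entropy_m: int | Literal["observed"] = 20
    high_cut: float = 0.45
    moderate_cut: float = 0.35
    neutral_majority: float = 0.5
    hydrophobic_cut: Optional[float] = None
    hydrophilic_cut: Optional[float] = None
    scale: HydrophobicityScale = NOZAKI_TANFORD
    classify_by: Literal["hydropathy", "majority"] = "hydropathy"

    def resolved_cuts(self) -> tuple[float, float]:
        mid = self.scale.midpoint
        hb = self.hydrophobic_cut if self.hydrophobic_cut is not None else mid
        hp = self.hydrophilic_cut if self.hydrophilic_cut is not None else mid
        return hb, hp


@dataclass(frozen=True)
class ColumnProfile:
    """Residue counts of one alignment column."""

    column: int
    counts: dict[str, int] = field(hash=False)
    gap_count: int = 0

    @property
    def n_obs(self) -> int:
        return sum(self.counts.values())

    @property
    def n_types(self) -> int:
        return sum(1 for v in self.counts.values() if v > 0)


@dataclass(frozen=True)
class ConservationRecord:
    column: int
    entropy: float  # S(i), nats; NaN for an all-gap column
    score: float  # C(i) in [0, 1]
    m: int
    bin: Bin


@dataclass(frozen=True)
class HydropathyRecord:
    column: int
    hydropathy_sum: float
    hydropathy_mean: float
    phys_class: PhysClass


def column_counts(aln: AlignedSequenceSet, column: int) -> ColumnProfile:
    """Count residue types and gaps in a 1-based column."""
    chars = aln.column(column)
    counts = Counter(c for c in chars if c != GAP)
    return ColumnProfile(
        column=column, counts=dict(counts), gap_count=chars.count(GAP)
    )


def shannon_entropy(profile: ColumnProfile) -> float:
    """Shannon entropy S(i) in nats of the non-gap residue composition.

    The sum runs over observed types with the convention 0·ln 0 = 0;
    gaps are not an amino-acid type and are excluded from the
    denominator.  Raises for an all-gap column (the gap rule is the
    caller's job there).
    """
    n = profile.n_obs
    if n < 1:
        raise ValueError(
            f"column {profile.column}: entropy undefined for all-gap column"
        )
    s = 0.0
    for count in profile.counts.values():
        if count > 0:
            p = count / n
            s -= p * math.log(p)
    return s


def conservation_score(S: float, m: int) -> float:
    """C = 1 - S/ln(m); 1 for an invariant column, 0 for uniform over m."""
    if m < 2:
        raise ValueError(f"m must be >= 2, got {m}")
    log_m = math.log(m)
    if S < -1e-12 or S > log_m + 1e-9:
        raise ValueError(f"entropy {S} outside [0, ln({m})={log_m:.4f}]")
    return min(1.0, max(0.0, 1.0 - S / log_m))


def bin_conservation(
    C: float, *, high_cut: float = 0.45, moderate_cut: float = 0.35
) -> Bin:
    """Partition a conservation score into high / moderate / low.

    The closed/half-open convention ``high: C >= 0.45``,
    ``moderate: 0.35 <= C < 0.45``, ``low: C < 0.35`` partitions [0, 1]
    without gaps.
    """
    if not 0.0 <= C <= 1.0:
        raise ValueError(f"conservation score {C} outside [0, 1]")
    if C >= high_cut:
        return "high"
    if C >= moderate_cut:
        return "moderate"
    return "low"


def apply_gap_rule(
    record: ConservationRecord, gap_count: int
) -> ConservationRecord:
    """Zero the score of any column with more than one gap.

    Such columns are considered non-conserved regardless of the residue
    composition of the remaining sequences.
    """
    if gap_count < 0:
        raise ValueError("gap_count must be >= 0")
    if gap_count > 1:
        return replace(record, score=0.0, bin="gap_zeroed")
    return record


def column_hydropathy(
    profile: ColumnProfile, scale: HydrophobicityScale = NOZAKI_TANFORD
) -> HydropathyRecord:
    """Hydropathy of a column: sum of count × hydrophobicity, and its mean."""
    n = profile.n_obs
    if n < 1:
        raise ValueError(
            f"column {profile.column}: hydropathy undefined for all-gap column"
        )
    total = sum(
        count * scale.values[res] for res, count in profile.counts.items()
    )
    return HydropathyRecord(
        column=profile.column,
        hydropathy_sum=total,
        hydropathy_mean=total / n,
        phys_class="unclassified",
    )


def classify_position(
    cons: ConservationRecord,
    hyd: HydropathyRecord,
    profile: ColumnProfile,
    cfg: ProfileConfig = ProfileConfig(),
) -> PhysClass:
    """Physicochemical class of a conserved column.

    Neutral if Gly/Ala/Pro together reach ``cfg.neutral_majority`` of the
    observed residues (these small residues recur in turns for structural
    rather than chemical reasons); otherwise hydrophobic or hydrophilic by
    the mean hydropathy against the configured cutoffs.  Only columns
    binned high or moderate are classified.
    """
    if cons.bin not in ("high", "moderate"):
        raise ValueError(
            f"column {cons.column}: only conserved columns are classified "
            f"(bin={cons.bin})"
        )
    n = profile.n_obs
    neutral_frac = (
        sum(profile.counts.get(r, 0) for r in NEUTRAL_RESIDUES) / n
    )
    if neutral_frac >= cfg.neutral_majority:
        return "neutral"
    if cfg.classify_by == "majority":
        top = max(profile.counts, key=lambda r: (profile.counts[r], r))
        value = cfg.scale.values[top]
    else:
        value = hyd.hydropathy_mean
    hb_cut, hp_cut = cfg.resolved_cuts()
    if value >= hb_cut:
        return "hydrophobic"
    if value <= hp_cut:
        return "hydrophilic"
    return "unclassified"


@dataclass(frozen=True)
class AlignmentProfile:
    """Result of :func:`profile_alignment`: one record pair per column."""

    conservation: tuple[ConservationRecord, ...]
    hydropathy: tuple[HydropathyRecord, ...]
    profiles: tuple[ColumnProfile, ...]
    histogram: dict[str, int] = field(hash=False)

    def class_counts(self) -> dict[tuple[Bin, PhysClass], int]:
        """Counts of (conservation bin, phys class) over classified columns."""
        out: Counter = Counter()
        for c, h in zip(self.conservation, self.hydropathy):
            if c.bin in ("high", "moderate") and h.phys_class != "unclassified":
                out[(c.bin, h.phys_class)] += 1
        return dict(out)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-column table (one row per alignment column)."""
        rows = []
        for c, h, p in zip(self.conservation, self.hydropathy, self.profiles):
            rows.append(
                {
                    "column": c.column,
                    "n_obs": p.n_obs,
                    "gap_count": p.gap_count,
                    "entropy_nats": c.entropy,
                    "conservation": c.score,
                    "bin": c.bin,
                    "hydropathy_sum": h.hydropathy_sum,
                    "hydropathy_mean": h.hydropathy_mean,
                    "phys_class": h.phys_class,
                }
            )
        return pd.DataFrame(rows)


def conservation_histogram(
    scores: Sequence[float], n_bins: int = 10
) -> dict[str, int]:
    """Histogram of conservation scores over equal-width bins on [0, 1]."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.asarray(scores, dtype=float), bins=edges)
    return {
        f"[{edges[i]:.2f},{edges[i + 1]:.2f})": int(counts[i])
        for i in range(n_bins)
    }


def profile_alignment(
    aln: AlignedSequenceSet, cfg: ProfileConfig = ProfileConfig()
) -> AlignmentProfile:
    """Score every column of an alignment.

    For each column: count residues, compute S(i) and C(i), apply the
    more-than-one-gap rule *after* scoring, bin the score, and attach the
    hydropathy record with the physicochemical class of conserved columns.
    All-gap columns (only possible with more than one sequence when every
    row is gapped, hence always gap-zeroed) get entropy NaN and score 0.
    """
    cons_records: list[ConservationRecord] = []
    hyd_records: list[HydropathyRecord] = []
    profiles: list[ColumnProfile] = []
    for col in range(1, aln.L + 1):
        prof = column_counts(aln, col)
        profiles.append(prof)
        if prof.n_obs == 0:
            # all-gap column; with N >= 2 the gap rule zeroes it anyway
            if prof.gap_count <= 1:
                raise ValueError(
                    f"column {col} is all-gap in a single-sequence alignment"
                )
            cons = ConservationRecord(
                column=col, entropy=float("nan"), score=0.0,
                m=20 if cfg.entropy_m == "observed" else int(cfg.entropy_m),
                bin="gap_zeroed",
            )
            hyd = HydropathyRecord(
                column=col, hydropathy_sum=0.0, hydropathy_mean=float("nan"),
                phys_class="unclassified",
            )
            cons_records.append(cons)
            hyd_records.append(hyd)
            continue
        m = (
            max(2, prof.n_types)
            if cfg.entropy_m == "observed"
            else int(cfg.entropy_m)
        )
        S = shannon_entropy(prof)
        C = conservation_score(S, m)
        cons = ConservationRecord(
            column=col, entropy=S, score=C, m=m,
            bin=bin_conservation(
                C, high_cut=cfg.high_cut, moderate_cut=cfg.moderate_cut
            ),
        )
        cons = apply_gap_rule(cons, prof.gap_count)
        hyd = column_hydropathy(prof, cfg.scale)
        if cons.bin in ("high", "moderate"):
            hyd = replace(
                hyd, phys_class=classify_position(cons, hyd, prof, cfg)
            )
        cons_records.append(cons)
        hyd_records.append(hyd)
    return AlignmentProfile(
        conservation=tuple(cons_records),
        hydropathy=tuple(hyd_records),
        profiles=tuple(profiles),
        histogram=conservation_histogram([c.score for c in cons_records]),
    )
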