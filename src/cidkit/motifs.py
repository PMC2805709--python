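"""Occupancy-based scanning for conserved column motifs.

A motif is a set of constrained slots at fixed column offsets from an
anchor; unconstrained intervening columns are wildcards ('x').  The two
motifs characteristic of the chitinase insertion domain are shipped as
defaults:

- ``YxR``       — tyrosine / any / arginine; the Tyr/Arg pair forms a
  pi-cation interaction and hydrogen bonds to a catalytic aspartate of
  the TIM barrel.
- ``[E/D]xx[V/I]`` — acidic / any / any / branched aliphatic, contacting
  the -1/-2 sugar subsites.

Matching is column-level: a slot matches when a configurable fraction of
the non-gap residues in its column belongs to the allowed set, and the
column is conserved (high or moderate bin).  This tolerates individual
substitutions, e.g. a serine standing in the [V/I] slot of one sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from cidkit.alignment import GAP, AlignedSequenceSet, ResidueMap
from cidkit.profiles import ConservationRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_OCCUPANCY = 0.5
CONSERVED_BINS = frozenset({"high", "moderate"})


@dataclass(frozen=True)
class MotifSlot:
    offset: int
    allowed_types: frozenset[str]
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY


@dataclass(frozen=True)
class MotifDefinition:
    """Ordered constrained slots at strictly increasing offsets (first 0)."""

    motif_id: str
    slots: tuple[MotifSlot, ...]

    def __post_init__(self) -> None:
        if not self.slots:
            raise ValueError(f"motif {self.motif_id!r} has no slots")
        offsets = [s.offset for s in self.slots]
        if offsets[0] != 0 or any(
            b <= a for a, b in zip(offsets, offsets[1:])
        ):
            raise ValueError(
                f"motif {self.motif_id!r}: offsets must start at 0 and "
                f"strictly increase, got {offsets}"
            )

    @property
    def span(self) -> int:
        return self.slots[-1].offset + 1


def yxr_motif(min_occupancy: float = DEFAULT_MIN_OCCUPANCY) -> MotifDefinition:
    return MotifDefinition(
        motif_id="YxR",
        slots=(
            MotifSlot(0, frozenset("Y"), min_occupancy),
            MotifSlot(2, frozenset("R"), min_occupancy),
        ),
    )


def edxxvi_motif(
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
) -> MotifDefinition:
    return MotifDefinition(
        motif_id="[E/D]xx[V/I]",
        slots=(
            MotifSlot(0, frozenset("ED"), min_occupancy),
            MotifSlot(3, frozenset("VI"), min_occupancy),
        ),
    )


def default_motifs(
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
) -> list[MotifDefinition]:
    return [yxr_motif(min_occupancy), edxxvi_motif(min_occupancy)]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence anchored at an alignment column.

    ``per_sequence`` maps each sequence id to the tuple of residue
    letters at the slot columns ('-' for a gap); ``matches`` records
    whether that particular sequence satisfies every slot's allowed set.
    """

    motif_id: str
    anchor_column: int
    slot_columns: tuple[int, ...]
    slot_occupancy: tuple[float, ...]
    per_sequence: dict[str, tuple[str, ...]] = field(hash=False)
    matches: dict[str, bool] = field(hash=False)


def _slot_occupancy(
    aln: AlignedSequenceSet, col: int, allowed: frozenset[str]
) -> float:
    chars = [c for c in aln.column(col) if c != GAP]
    if not chars:
        return 0.0
    return sum(1 for c in chars if c in allowed) / len(chars)


def scan_motifs(
    aln: AlignedSequenceSet,
    conservation: Sequence[ConservationRecord],
    defs: Optional[Sequence[MotifDefinition]] = None,
    *,
    require_gap_free_x: bool = False,
) -> list[MotifHit]:
    """Scan every anchor column for each motif definition.

    A hit is reported at anchor *a* iff every slot *s* satisfies both
    (i) occupancy: the fraction of non-gap residues at column
    ``a + offset_s`` belonging to the allowed set reaches the slot's
    ``min_occupancy``, and (ii) conservation: that column's bin is high
    or moderate.  Wildcard columns are unconstrained unless
    ``require_gap_free_x`` is set, in which case a majority of sequences
    must be ungapped there.  Anchors whose motif span extends past the
    alignment end are skipped (logged at debug level).
    """
    if defs is None:
        defs = default_motifs()
    if len(conservation) != aln.L:
        raise ValueError(
            f"conservation records cover {len(conservation)} columns, "
            f"alignment has {aln.L}"
        )
    bins = {rec.column: rec.bin for rec in conservation}
    hits: list[MotifHit] = []
    for mdef in defs:
        for anchor in range(1, aln.L + 1):
            last = anchor + mdef.slots[-1].offset
            if last > aln.L:
                logger.debug(
                    "motif %s at anchor %d extends past alignment end",
                    mdef.motif_id, anchor,
                )
                continue
            occupancies = []
            ok = True
            for slot in mdef.slots:
                col = anchor + slot.offset
                if bins[col] not in CONSERVED_BINS:
                    ok = False
                    break
                occ = _slot_occupancy(aln, col, slot.allowed_types)
                if occ < slot.min_occupancy:
                    ok = False
                    break
                occupancies.append(occ)
            if not ok:
                continue
            if require_gap_free_x:
                wild = set(range(anchor, last + 1)) - {
                    anchor + s.offset for s in mdef.slots
                }
                if any(
                    aln.column(c).count(GAP) > aln.N / 2 for c in wild
                ):
                    continue
            slot_cols = tuple(anchor + s.offset for s in mdef.slots)
            per_seq = {
                rec.seq_id: tuple(rec.residues[c - 1] for c in slot_cols)
                for rec in aln.records
            }
            matches = {
                sid: all(
                    ch in slot.allowed_types
                    for ch, slot in zip(letters, mdef.slots)
                )
                for sid, letters in per_seq.items()
            }
            hits.append(
                MotifHit(
                    motif_id=mdef.motif_id,
                    anchor_column=anchor,
                    slot_columns=slot_cols,
                    slot_occupancy=tuple(occupancies),
                    per_sequence=per_seq,
                    matches=matches,
                )
            )
    return hits


def hit_to_residues(hit: MotifHit, rmap: ResidueMap) -> list[str]:
    """Slot labels of a hit in one sequence's structure numbering.

    Returns labels like ``'Y267'`` per slot, or ``'gap'`` where that
    sequence is gapped at the slot column.
    """
    letters = hit.per_sequence[rmap.seq_id]
    labels = []
    for col, letter in zip(hit.slot_columns, letters):
        num = rmap.column_to_residue[col]
        labels.append("gap" if num is None else f"{letter}{num}")
    return labels


def load_motif_definitions(path: str | Path) -> list[MotifDefinition]:
    """Read motif definitions from JSON.

    Format: a list of ``{"motif_id": ..., "slots": [{"offset": int,
    "types": "YR...", "min_occupancy": float?}, ...]}``.
    """
    data = json.loads(Path(path).read_text())
    defs = []
    for entry in data:
        defs.append(
            MotifDefinition(
                motif_id=entry["motif_id"],
                slots=tuple(
                    MotifSlot(
                        offset=s["offset"],
                        allowed_types=frozenset(s["types"]),
                        min_occupancy=s.get(
                            "min_occupancy", DEFAULT_MIN_OCCUPANCY
                        ),
                    )
                    for s in entry["slots"]
                ),
            )
        )
    return defs


def hits_to_tsv(
    hits: Sequence[MotifHit], rmaps: Optional[Sequence[ResidueMap]] = None
) -> str:
    """TSV report of hits, optionally with structure residue labels."""
    header = ["motif_id", "anchor_column", "slot_columns", "slot_occupancy"]
    rmaps = rmaps or []
    header += [f"residues_{m.seq_id}" for m in rmaps]
    lines = ["\t".join(header)]
    for hit in hits:
        row = [
            hit.motif_id,
            str(hit.anchor_column),
            ",".join(map(str, hit.slot_columns)),
            ",".join(f"{o:.6g}" for o in hit.slot_occupancy),
        ]
        row += [",".join(hit_to_residues(hit, m)) for m in rmaps]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
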