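"""Aligned protein sequence sets and residue-number bookkeeping.

All column indices in this package are **1-based and inclusive on both
ends**, matching how positions in protein alignments are conventionally
cited (e.g. "Tyr267").  The alphabet is the 20 canonical amino acids plus
the gap character ``'-'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
#: Ambiguity / non-canonical one-letter codes rejected by default.
AMBIGUOUS: str = "BZXJUO"

#: Kingdom/lineage tags used in CID alignments: Archaea, Bacteria, Fungi,
#: Plantae, early eukaryotes, early Animalia, mammals, vertebrates.
KINGDOM_TAGS = frozenset({"Ar", "B", "F", "P", "EE", "EA", "M", "V"})


class AlignmentFormatError(ValueError):
    """Raised for ragged alignments or otherwise malformed input."""


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside the alphabet."""


@dataclass(frozen=True)
class AlignedRecord:
    """One gapped sequence in an alignment."""

    seq_id: str
    residues: str
    kingdom_tag: Optional[str] = None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedSequenceSet:
    """Equal-length gapped protein sequences with taxon metadata.

    Invariants (checked at construction): all records share one length
    ``L >= 1``; every character is a canonical amino acid or ``'-'``;
    sequence ids are unique.
    """

    records: tuple[AlignedRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentFormatError("alignment contains no sequences")
        L = len(self.records[0])
        if L < 1:
            raise AlignmentFormatError(
                f"record {self.records[0].seq_id!r} is empty"
            )
        seen: set[str] = set()
        allowed = set(AMINO_ACIDS + GAP)
        for k, rec in enumerate(self.records, start=1):
            if len(rec) != L:
                raise AlignmentFormatError(
                    f"record {k} ({rec.seq_id!r}) has length {len(rec)}, "
                    f"expected {L}"
                )
            if rec.seq_id in seen:
                raise AlignmentFormatError(f"duplicate seq_id {rec.seq_id!r}")
            seen.add(rec.seq_id)
            for pos, ch in enumerate(rec.residues, start=1):
                if ch not in allowed:
                    raise AlphabetError(
                        f"record {rec.seq_id!r}: illegal character {ch!r} "
                        f"at column {pos}"
                    )

    @property
    def N(self) -> int:
        """Number of sequences."""
        return len(self.records)

    @property
    def L(self) -> int:
        """Alignment length in columns."""
        return len(self.records[0])

    @property
    def seq_ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    def record(self, seq_id: str) -> AlignedRecord:
        for rec in self.records:
            if rec.seq_id == seq_id:
                return rec
        raise KeyError(f"unknown seq_id {seq_id!r}")

    def column(self, col: int) -> str:
        """Return the characters of 1-based column ``col`` top to bottom."""
        if not 1 <= col <= self.L:
            raise IndexError(f"column {col} out of range 1..{self.L}")
        return "".join(rec.residues[col - 1] for rec in self.records)


def _normalize(seq: str, seq_id: str, map_ambiguous_to_gap: bool) -> str:
    """Uppercase, turn '.' into '-', and police the alphabet."""
    out = []
    for pos, ch in enumerate(seq.upper(), start=1):
        if ch == ".":
            ch = GAP
        if ch in AMBIGUOUS:
            if map_ambiguous_to_gap:
                ch = GAP
            else:
                raise AlphabetError(
                    f"record {seq_id!r}: ambiguity code {ch!r} at column "
                    f"{pos} (use map_ambiguous_to_gap=True to accept)"
                )
        out.append(ch)
    return "".join(out)


def _parse_kingdom_tag(description: str) -> Optional[str]:
    # ids of the form "name|TAG" carry a lineage tag
    if "|" in description:
        tag = description.rsplit("|", 1)[1]
        if tag in KINGDOM_TAGS:
            return tag
    return None


def read_alignment(
    path: str | Path, *, map_ambiguous_to_gap: bool = False
) -> AlignedSequenceSet:
    """Read an aligned-FASTA file into an :class:`AlignedSequenceSet`.

    Lowercase letters are uppercased and ``'.'`` gaps become ``'-'``.
    Ambiguity codes (B, Z, X, J, U, O) are rejected unless
    ``map_ambiguous_to_gap`` is set, in which case they become gaps: the
    entropy statistic downstream is defined over amino-acid types only.
    A trailing ``|TAG`` on a FASTA id (TAG one of Ar, B, F, P, EE, EA, M,
    V) is parsed as a kingdom/lineage tag.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            AlignedRecord(
                seq_id=rec.id,
                residues=_normalize(str(rec.seq), rec.id, map_ambiguous_to_gap),
                kingdom_tag=_parse_kingdom_tag(rec.id),
            )
        )
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    return AlignedSequenceSet(records=tuple(records))


def write_alignment(aln: AlignedSequenceSet, path: str | Path) -> None:
    """Write the alignment as aligned FASTA (round-trips with read)."""
    seqs = [
        SeqRecord(Seq(rec.residues), id=rec.seq_id, description="")
        for rec in aln.records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def from_sequences(
    pairs: Iterable[tuple[str, str]],
    *,
    kingdom_tags: Optional[dict[str, str]] = None,
) -> AlignedSequenceSet:
    """Build an alignment from ``(seq_id, residues)`` pairs (test helper)."""
    tags = kingdom_tags or {}
    return AlignedSequenceSet(
        records=tuple(
            AlignedRecord(seq_id=i, residues=s, kingdom_tag=tags.get(i))
            for i, s in pairs
        )
    )


def extract_region(
    aln: AlignedSequenceSet, first_col: int, last_col: int
) -> AlignedSequenceSet:
    """Slice columns ``[first_col, last_col]`` (1-based, inclusive).

    This is how a domain such as the CID is cut out of a full-length
    chitinase alignment once its boundaries are known.
    """
    if not (1 <= first_col <= last_col <= aln.L):
        raise IndexError(
            f"column range {first_col}..{last_col} invalid for alignment of "
            f"length {aln.L}"
        )
    return AlignedSequenceSet(
        records=tuple(
            AlignedRecord(
                seq_id=rec.seq_id,
                residues=rec.residues[first_col - 1 : last_col],
                kingdom_tag=rec.kingdom_tag,
            )
            for rec in aln.records
        )
    )


@dataclass(frozen=True)
class ResidueMap:
    """Map alignment columns of one sequence to structure residue numbers.

    ``column_to_residue[col]`` is the residue number for a non-gap column,
    or ``None`` where the sequence has a gap.  Residue numbers increase
    strictly across non-gap columns.
    """

    seq_id: str
    start_number: int
    column_to_residue: dict[int, Optional[int]] = field(hash=False)

    def label(self, col: int) -> str:
        """Residue label like ``'267'`` or ``'gap'`` for a column."""
        num = self.column_to_residue[col]
        return "gap" if num is None else str(num)

    def n_residues(self) -> int:
        return sum(1 for v in self.column_to_residue.values() if v is not None)


def build_residue_map(
    aln: AlignedSequenceSet, seq_id: str, start_number: int
) -> ResidueMap:
    """Number the non-gap columns of one record from ``start_number`` up.

    The k-th non-gap column maps to ``start_number + k - 1``; gap columns
    map to ``None``.  ``start_number`` is typically the residue number of
    the domain's first residue in a crystal structure, so that motif hits
    can be reported with structure numbering (e.g. Tyr267 in human
    chitotriosidase, PDB 1LG1).
    """
    rec = aln.record(seq_id)  # raises KeyError for unknown ids
    mapping: dict[int, Optional[int]] = {}
    k = 0
    for col, ch in enumerate(rec.residues, start=1):
        if ch == GAP:
            mapping[col] = None
        else:
            mapping[col] = start_number + k
            k += 1
    return ResidueMap(
        seq_id=seq_id, start_number=start_number, column_to_residue=mapping
    )


def residue_map_to_tsv(rmap: ResidueMap, aln: AlignedSequenceSet) -> str:
    """TSV export: column_index, residue_number, residue_letter."""
    rec = aln.record(rmap.seq_id)
    lines = ["column_index\tresidue_number\tresidue_letter"]
    for col in sorted(rmap.column_to_residue):
        lines.append(
            f"{col}\t{rmap.label(col)}\t{rec.residues[col - 1]}"
        )
    return "\n".join(lines) + "\n"
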