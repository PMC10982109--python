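"""Input handling: FASTA sequences and BED-like gene tables.

Sequence sets are validated against the submission limits (2-300 sequences,
each at most 20 Mbp). All internal coordinates are 0-based, half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

MAX_SEQUENCES = 300
MAX_SEQ_LENGTH = 20_000_000
MIN_SEQUENCES = 2

# A/C/G/T plus N; other IUPAC ambiguity codes are rejected so that
# alignment scoring stays well-defined.
_VALID_BASES = frozenset("ACGTN")
_COLOR_RE = re.compile(r"^#[0-9a-fA-F]{6}$")


class InputError(ValueError):
    """Raised for any invalid user input (FASTA, gene table, set limits)."""


@dataclass
class GeneFeature:
    """One gene interval on a sequence, BED convention (0-based, end-exclusive)."""

    seq_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    label: str | None = None
    color: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"malformed strand {self.strand!r} for {self.seq_id}")
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid gene interval [{self.start}, {self.end}) on {self.seq_id}: "
                "start must be >= 0 and < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SeqRecord:
    """A named nucleotide sequence, optionally circular, with gene features."""

    id: str
    sequence: str
    circular: bool = False
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains non-IUPAC or ambiguous characters: "
                f"{','.join(sorted(bad))} (only A,C,G,T,N accepted)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> str:
        return str(Seq(self.sequence).reverse_complement())


@dataclass
class InputSet:
    """A validated, ordered sequence set ready for pairwise comparison."""

    records: list[SeqRecord]
    mode: Literal["nucleotide", "translated"] = "nucleotide"

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, seq_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)


def read_fasta(path: str | Path, circular_ids: Iterable[str] = ()) -> list[SeqRecord]:
    """Read FASTA into SeqRecords.

    Ids are the first whitespace-delimited header token; sequences are
    uppercased; file order is preserved. Duplicate ids, empty files and
    invalid characters are hard errors. Sequences whose id appears in
    ``circular_ids`` are flagged circular (circularity is declared, not
    auto-detected).
    """
    circular = set(circular_ids)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SeqRecord(id=rec.id, sequence=str(rec.seq), circular=rec.id in circular)
        )
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    unknown = circular - seen
    if unknown:
        raise InputError(f"circular ids not present in FASTA: {sorted(unknown)}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records to FASTA (fixed line width, deterministic output)."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def validate_input_set(
    records: list[SeqRecord], mode: Literal["nucleotide", "translated"] = "nucleotide"
) -> InputSet:
    """Enforce the submission limits: 2-300 sequences, each <= 20 Mbp."""
    n = len(records)
    if n < MIN_SEQUENCES:
        raise InputError(f"too few sequences: got {n}, need at least {MIN_SEQUENCES}")
    if n > MAX_SEQUENCES:
        raise InputError(f"too many sequences: got {n}, maximum is {MAX_SEQUENCES}")
    for r in records:
        if r.length > MAX_SEQ_LENGTH:
            raise InputError(
                f"sequence {r.id!r} is {r.length} bp, exceeding the "
                f"{MAX_SEQ_LENGTH} bp per-sequence limit"
            )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate sequence ids: {dup}")
    return InputSet(records=list(records), mode=mode)


def read_gene_table(path: str | Path, records: list[SeqRecord]) -> list[SeqRecord]:
    """Attach gene features from a BED-like TSV to their sequences.

    Columns: seq_id, start, end, strand (required); label, color "#rrggbb"
    (optional). Coordinates are BED convention: 0-based start, exclusive end.
    Lines starting with '#' are ignored. Rows referencing unknown sequence
    ids, inverted intervals, out-of-range coordinates or malformed strands
    are hard errors naming the offending row.
    """
    by_id = {r.id: r for r in records}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise InputError(
                    f"{path}:{lineno}: expected at least 4 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seq_id, start_s, end_s, strand = cols[:4]
            if seq_id not in by_id:
                raise InputError(f"{path}:{lineno}: unknown sequence id {seq_id!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise InputError(
                    f"{path}:{lineno}: start {start} >= end {end} on {seq_id!r}"
                )
            rec = by_id[seq_id]
            if start < 0 or end > rec.length:
                raise InputError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside "
                    f"sequence {seq_id!r} of length {rec.length}"
                )
            label = cols[4] if len(cols) > 4 and cols[4] else None
            color = cols[5] if len(cols) > 5 and cols[5] else None
            if color is not None and not _COLOR_RE.match(color):
                raise InputError(
                    f"{path}:{lineno}: color {color!r} is not of the form #rrggbb"
                )
            rec.genes.append(
                GeneFeature(seq_id=seq_id, start=start, end=end, strand=strand,
                            label=label, color=color)
            )
    return records
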