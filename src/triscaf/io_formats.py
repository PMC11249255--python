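"""External file formats: FASTA, 4DN pairs, AGP v2.1, and truth layouts.

All coordinates are 0-based half-open internally.  File dialects that
mandate 1-based inclusive coordinates (AGP, pairs) are converted at the
boundary, in one place, so the rest of the package never sees them.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A malformed record in an external file; the message names the line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, upper-cased on construction."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"illegal characters {sorted(bad)} in sequence {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class ContactPair:
    """One deduplicated Hi-C read pair as two (reference, position) loci.

    Stored canonically with ``(ref1, pos1) <= (ref2, pos2)`` so each
    physical pair has a single representation.  Positions are 0-based.
    """

    ref1: str
    pos1: int
    ref2: str
    pos2: int

    @classmethod
    def make(cls, ref1: str, pos1: int, ref2: str, pos2: int) -> "ContactPair":
        if (ref1, pos1) <= (ref2, pos2):
            return cls(ref1, pos1, ref2, pos2)
        return cls(ref2, pos2, ref1, pos1)

    @property
    def is_cis(self) -> bool:
        return self.ref1 == self.ref2


@dataclass(frozen=True)
class AGPRow:
    """One row of an AGP v2.1 file (1-based inclusive object coordinates)."""

    object: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str          # 'W' (contig) or 'U' (gap of unknown size type)
    # W fields
    component_id: str | None = None
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    # U fields
    gap_length: int | None = None
    gap_type: str = "scaffold"
    linkage: str = "yes"

    def __post_init__(self) -> None:
        if self.component_type not in ("W", "U"):
            raise ValueError(f"unsupported component type {self.component_type!r}")
        if self.component_type == "W":
            if self.orientation not in ("+", "-"):
                raise ValueError("W row requires orientation '+' or '-'")
            if (self.object_end - self.object_beg
                    != self.component_end - self.component_beg):
                raise ValueError(
                    f"W row span mismatch on object {self.object!r} part {self.part_number}")
        else:
            if self.gap_length is None or self.gap_length <= 0:
                raise ValueError("U row requires a positive gap_length")
            if self.object_end - self.object_beg + 1 != self.gap_length:
                raise ValueError("U row span must equal gap_length")


@dataclass
class TruthLayout:
    """Ordered, oriented contig list per chromosome; ground truth for evaluation."""

    chromosomes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom, entries in self.chromosomes.items():
            for contig, orient in entries:
                if orient not in ("+", "-"):
                    raise ValueError(f"bad orientation {orient!r} for {contig!r}")
                if contig in seen:
                    raise ValueError(f"contig {contig!r} appears more than once")
                seen.add(contig)

    @property
    def contigs(self) -> set[str]:
        return {c for entries in self.chromosomes.values() for c, _ in entries}

    def rank_table(self) -> dict[str, tuple[str, int, str]]:
        """contig -> (chromosome, 0-based rank, truth orientation)."""
        out = {}
        for chrom, entries in self.chromosomes.items():
            for rank, (contig, orient) in enumerate(entries):
                out[contig] = (chrom, rank, orient)
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file.

    Raises :class:`FormatError` with a line number on malformed headers,
    illegal sequence characters, or duplicated ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(lineno: int) -> None:
        nonlocal current_id, chunks
        if current_id is None:
            return
        seq = "".join(chunks).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: illegal sequence character(s) {sorted(bad)} in record "
                f"{current_id!r} (header at line {header_line})")
        records.append(SequenceRecord(current_id, seq))
        current_id, chunks = None, []

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(lineno)
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                if name in seen:
                    raise FormatError(f"{path}: duplicate record id {name!r} at line {lineno}")
                seen.add(name)
                current_id = name
                header_line = lineno
            else:
                if current_id is None:
                    raise FormatError(f"{path}: sequence before any header at line {lineno}")
                chunks.append(line.strip())
        flush(-1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                line_width: int = 60) -> None:
    """Write records as FASTA with fixed line width."""
    if line_width <= 0:
        raise ValueError("line_width must be positive")
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# 4DN pairs
# ---------------------------------------------------------------------------

_PAIRS_HEADER = "## pairs format v1.0"
_PAIRS_COLUMNS = "#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2"


def read_pairs(path: str | Path,
               sequences: Sequence[SequenceRecord] | dict[str, int] | None = None,
               ) -> list[ContactPair]:
    """Read a 4DN-dialect pairs file into canonical :class:`ContactPair` loci.

    Columns: readID, chrom1, pos1, chrom2, pos2[, strand1, strand2]; strands
    are ignored.  File positions are 1-based and converted to 0-based.  When
    ``sequences`` is given (records or an id->length map), pairs referencing
    unknown references are dropped with a logged count and positions are
    validated against reference lengths.
    """
    lengths: dict[str, int] | None = None
    if sequences is not None:
        if isinstance(sequences, dict):
            lengths = dict(sequences)
        else:
            lengths = {r.id: r.length for r in sequences}

    pairs: list[ContactPair] = []
    dropped = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}: expected >=5 tab-separated columns at line {lineno}")
            _, ref1, p1s, ref2, p2s = fields[:5]
            try:
                pos1, pos2 = int(p1s) - 1, int(p2s) - 1
            except ValueError:
                raise FormatError(f"{path}: non-integer position at line {lineno}") from None
            if pos1 < 0 or pos2 < 0:
                raise FormatError(f"{path}: position < 1 at line {lineno}")
            if lengths is not None:
                if ref1 not in lengths or ref2 not in lengths:
                    dropped += 1
                    continue
                if pos1 >= lengths[ref1] or pos2 >= lengths[ref2]:
                    raise FormatError(f"{path}: position beyond reference end at line {lineno}")
            pairs.append(ContactPair.make(ref1, pos1, ref2, pos2))
    if dropped:
        logger.warning("%s: dropped %d pair(s) referencing unknown sequences", path, dropped)
    return pairs


def write_pairs(pairs: Iterable[ContactPair], path: str | Path) -> None:
    """Write canonical pairs in the 4DN dialect (1-based positions, '.' strands)."""
    with _open_text(path, "wt") as fh:
        fh.write(_PAIRS_HEADER + "\n")
        fh.write(_PAIRS_COLUMNS + "\n")
        for i, p in enumerate(pairs):
            fh.write(f"r{i}\t{p.ref1}\t{p.pos1 + 1}\t{p.ref2}\t{p.pos2 + 1}\t.\t.\n")


# ---------------------------------------------------------------------------
# AGP v2.1
# ---------------------------------------------------------------------------

def validate_agp(rows: Sequence[AGPRow]) -> None:
    """Check the tiling invariant: rows of each object cover [1..end] without
    overlap or holes and part numbers run consecutively from 1."""
    by_object: dict[str, list[AGPRow]] = {}
    for row in rows:
        by_object.setdefault(row.object, []).append(row)
    for obj, obj_rows in by_object.items():
        expected_beg, expected_part = 1, 1
        for row in obj_rows:
            if row.part_number != expected_part:
                raise ValueError(
                    f"AGP object {obj!r}: part_number {row.part_number}, expected {expected_part}")
            if row.object_beg != expected_beg:
                raise ValueError(
                    f"AGP object {obj!r}: hole or overlap at part {row.part_number} "
                    f"(object_beg {row.object_beg}, expected {expected_beg})")
            if row.object_end < row.object_beg:
                raise ValueError(f"AGP object {obj!r}: empty span at part {row.part_number}")
            expected_beg = row.object_end + 1
            expected_part += 1


def write_agp(rows: Sequence[AGPRow], path: str | Path) -> None:
    validate_agp(rows)
    with _open_text(path, "wt") as fh:
        fh.write("##agp-version\t2.1\n")
        for r in rows:
            if r.component_type == "W":
                fh.write("\t".join(map(str, (
                    r.object, r.object_beg, r.object_end, r.part_number, "W",
                    r.component_id, r.component_beg, r.component_end, r.orientation))) + "\n")
            else:
                fh.write("\t".join(map(str, (
                    r.object, r.object_beg, r.object_end, r.part_number, "U",
                    r.gap_length, r.gap_type, r.linkage, "proximity_ligation"))) + "\n")


def read_agp(path: str | Path) -> list[AGPRow]:
    rows: list[AGPRow] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}: expected 9 columns at line {lineno}")
            try:
                obj, beg, end, part, ctype = f[0], int(f[1]), int(f[2]), int(f[3]), f[4]
                if ctype == "W":
                    rows.append(AGPRow(obj, beg, end, part, "W",
                                       component_id=f[5], component_beg=int(f[6]),
                                       component_end=int(f[7]), orientation=f[8]))
                elif ctype in ("U", "N"):
                    rows.append(AGPRow(obj, beg, end, part, "U",
                                       gap_length=int(f[5]), gap_type=f[6], linkage=f[7]))
                else:
                    raise FormatError(
                        f"{path}: unsupported component type {ctype!r} at line {lineno}")
            except ValueError as exc:
                raise FormatError(f"{path}: {exc} at line {lineno}") from None
    validate_agp(rows)
    return rows


# ---------------------------------------------------------------------------
# truth layout TSV
# ---------------------------------------------------------------------------

def write_layout(layout: TruthLayout, path: str | Path) -> None:
    """Write the layout as TSV with columns chrom, rank, contig_id, orientation."""
    with _open_text(path, "wt") as fh:
        fh.write("#chrom\trank\tcontig_id\torientation\n")
        for chrom, entries in layout.chromosomes.items():
            for rank, (contig, orient) in enumerate(entries, start=1):
                fh.write(f"{chrom}\t{rank}\t{contig}\t{orient}\n")


def read_layout(path: str | Path) -> TruthLayout:
    chroms: dict[str, list[tuple[str, str]]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise FormatError(f"{path}: expected 4 columns at line {lineno}")
            chrom, rank_s, contig, orient = f
            try:
                rank = int(rank_s)
            except ValueError:
                raise FormatError(f"{path}: non-integer rank at line {lineno}") from None
            entries = chroms.setdefault(chrom, [])
            if rank != len(entries) + 1:
                raise FormatError(f"{path}: non-consecutive rank {rank} at line {lineno}")
            entries.append((contig, orient))
    return TruthLayout(chroms)
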