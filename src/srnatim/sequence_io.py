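"""Transcript input and the relative coordinate convention.

Positions around a translation start are given in the 1-based biologist
convention with no position 0: +1 is the first base of the start codon,
-1 the base immediately upstream.  All window extraction and reporting
uses this convention; absolute coordinates are plain 0-based Python
indices into the transcript sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .nearest_neighbor import normalize_rna

START_CODONS = frozenset({"AUG", "GUG", "UUG"})


@dataclass(frozen=True)
class RelativeInterval:
    """Closed interval in start-codon-relative coordinates (no position 0)."""

    rel_start: int
    rel_end: int

    def __post_init__(self) -> None:
        if self.rel_start == 0 or self.rel_end == 0:
            raise ValueError("relative coordinates have no position 0")
        if self.rel_start > self.rel_end:
            raise ValueError(
                f"empty interval: rel_start={self.rel_start} > rel_end={self.rel_end}"
            )

    @property
    def length(self) -> int:
        """Number of nucleotide positions covered (position 0 does not exist)."""
        n = self.rel_end - self.rel_start + 1
        if self.rel_start < 0 < self.rel_end:
            n -= 1
        return n

    def __str__(self) -> str:  # Table-style "(-12)..+18"
        def fmt(x: int) -> str:
            return f"({x})" if x < 0 else f"+{x}"

        return f"{fmt(self.rel_start)}..{fmt(self.rel_end)}"


def rel_to_linear(rel: int) -> int:
    """Map the gapped relative axis onto contiguous integers (+1 -> 0, -1 -> -1)."""
    if rel == 0:
        raise ValueError("relative position 0 does not exist")
    return rel - 1 if rel > 0 else rel


def linear_to_rel(lin: int) -> int:
    return lin + 1 if lin >= 0 else lin


def intervals_overlap(a: RelativeInterval, b: RelativeInterval) -> bool:
    """True iff the two relative intervals share at least one position."""
    return max(rel_to_linear(a.rel_start), rel_to_linear(b.rel_start)) <= min(
        rel_to_linear(a.rel_end), rel_to_linear(b.rel_end)
    )


@dataclass(frozen=True)
class Transcript:
    """An mRNA sequence with an annotated translation start.

    ``start_pos`` is the 0-based index of the first base of the start
    codon.  Records whose annotated codon is not a recognized bacterial
    start (AUG/GUG/UUG) are kept but flagged via ``start_codon_valid``.
    """

    id: str
    sequence: str
    start_pos: int
    source: str | None = None

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence, context=f"transcript {self.id!r}")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        if not 0 <= self.start_pos <= len(seq) - 3:
            raise ValueError(
                f"transcript {self.id!r}: start_pos {self.start_pos} outside "
                f"[0, {len(seq) - 3}]"
            )

    @property
    def start_codon(self) -> str:
        return self.sequence[self.start_pos : self.start_pos + 3]

    @property
    def start_codon_valid(self) -> bool:
        return self.start_codon in START_CODONS


def relative_to_absolute(t: Transcript, rel: int) -> int:
    """Convert a relative position to a 0-based index (+1 -> start_pos)."""
    return t.start_pos + rel_to_linear(rel)


def absolute_to_relative(t: Transcript, pos: int) -> int:
    """Inverse of :func:`relative_to_absolute`."""
    return linear_to_rel(pos - t.start_pos)


@dataclass(frozen=True)
class WindowExtract:
    """A transcript slice with its clipping provenance."""

    sequence: str
    abs_start: int  # 0-based inclusive; meaningful only if sequence non-empty
    abs_end: int  # 0-based inclusive
    clipped_5p: bool
    clipped_3p: bool

    @property
    def empty(self) -> bool:
        return not self.sequence


def extract_window(t: Transcript, w: RelativeInterval) -> WindowExtract:
    """Slice the transcript under ``w``, clipping silently at both ends.

    A window entirely outside the transcript yields an empty, fully
    flagged extract rather than an exception, so that genes close to a
    transcript boundary remain screenable.
    """
    lo = relative_to_absolute(t, w.rel_start)
    hi = relative_to_absolute(t, w.rel_end)
    clip5 = lo < 0
    clip3 = hi > len(t.sequence) - 1
    lo_c = max(lo, 0)
    hi_c = min(hi, len(t.sequence) - 1)
    if lo_c > hi_c:
        return WindowExtract("", 0, -1, True, True)
    return WindowExtract(t.sequence[lo_c : hi_c + 1], lo_c, hi_c, clip5, clip3)


def load_annotation(path: str | Path) -> dict[str, int]:
    """Read a 2+-column TSV of (record id, 0-based start offset)."""
    table: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
        table[parts[0]] = int(parts[1])
    return table


def load_transcripts(
    fasta_path: str | Path,
    annotation: str | Path | Mapping[str, int] | int,
) -> list[Transcript]:
    """Load transcripts from FASTA plus a start-codon annotation.

    ``annotation`` is either a TSV path / mapping of per-record 0-based
    start offsets, or a single integer offset applied to every record.
    A record with no annotation entry is an error naming the record.
    """
    if isinstance(annotation, (str, Path)):
        table: Mapping[str, int] | None = load_annotation(annotation)
    elif isinstance(annotation, Mapping):
        table = annotation
    else:
        table = None  # uniform integer offset rule

    transcripts: list[Transcript] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if table is None:
            offset = int(annotation)  # type: ignore[arg-type]
        elif rec.id in table:
            offset = table[rec.id]
        else:
            raise ValueError(
                f"record {rec.id!r} in {fasta_path} has no start annotation"
            )
        transcripts.append(
            Transcript(rec.id, str(rec.seq), offset, source=str(fasta_path))
        )
    return transcripts


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as an unwrapped FASTA file."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
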