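"""Genome Index Splitter: optimal chunk length and the chromosome split table.

The splitter turns a genome index and a core budget into a chromosome split
table (CST): a 4-column table ``(ChrName, Chunk_no, Start, End)`` of disjoint
1-based inclusive intervals that partition every chromosome.  Downstream,
each CST row becomes one independent joint-genotyping job (scatter) whose
outputs are reassembled genome-wide (gather).

The chunk length is derived from the *largest* chromosome in three steps:
locate the largest chromosome length L; find the largest divisor of L within
the core budget ("fair" equal chunks); divide.  The same chunk length is then
applied uniformly to every chromosome, so only the last chunk of each
chromosome may be short.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Dict, Iterator, List, Tuple

from .errors import ParseError, ValidationError
from .genome_index import GenomeIndex, largest_chromosome

__all__ = [
    "ChunkInterval",
    "ChromosomeSplitTable",
    "optimal_divisor",
    "chunk_length_for",
    "build_cst",
    "write_cst",
    "read_cst",
]


@dataclass(frozen=True, order=True)
class ChunkInterval:
    """One disjoint variant interval: 1-based inclusive [start, end].

    ``chunk_no`` restarts at 1 for every chromosome.
    """

    chrom: str
    chunk_no: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.chunk_no < 1:
            raise ValidationError(f"chunk_no must be >= 1, got {self.chunk_no}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"bad interval {self.chrom}:{self.start}-{self.end} (need 1 <= start <= end)"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def interval_string(self) -> str:
        """The ``chrom:start-end`` form consumed by variant callers (-L)."""
        return f"{self.chrom}:{self.start}-{self.end}"

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class ChromosomeSplitTable:
    """Ordered chunk intervals grouped by genome-index chromosome order."""

    chunk_length: int
    entries: Tuple[ChunkInterval, ...]

    def __post_init__(self) -> None:
        if self.chunk_length < 1:
            raise ValidationError(f"chunk_length must be >= 1, got {self.chunk_length}")
        self._validate()

    def _validate(self) -> None:
        prev: ChunkInterval | None = None
        seen_chroms: set[str] = set()
        for entry in self.entries:
            if prev is None or entry.chrom != prev.chrom:
                if entry.chrom in seen_chroms:
                    raise ValidationError(
                        f"chromosome {entry.chrom!r} appears in non-contiguous blocks"
                    )
                seen_chroms.add(entry.chrom)
                if entry.chunk_no != 1:
                    raise ValidationError(
                        f"{entry.chrom}: first chunk must be numbered 1, got {entry.chunk_no}"
                    )
                if entry.start != 1:
                    raise ValidationError(
                        f"{entry.chrom}: first chunk must start at 1, got {entry.start}"
                    )
            else:
                if entry.chunk_no != prev.chunk_no + 1:
                    raise ValidationError(
                        f"{entry.chrom}: chunk numbering jumps {prev.chunk_no} -> {entry.chunk_no}"
                    )
                if entry.start != prev.end + 1:
                    raise ValidationError(
                        f"{entry.chrom} chunk {entry.chunk_no}: start {entry.start} "
                        f"!= previous end {prev.end} + 1 (gap or overlap)"
                    )
                if prev.span != self.chunk_length:
                    raise ValidationError(
                        f"{entry.chrom} chunk {prev.chunk_no}: non-final chunk has span "
                        f"{prev.span} != chunk_length {self.chunk_length}"
                    )
            if entry.span > self.chunk_length:
                raise ValidationError(
                    f"{entry.chrom} chunk {entry.chunk_no}: span {entry.span} exceeds "
                    f"chunk_length {self.chunk_length}"
                )
            prev = entry

    def __iter__(self) -> Iterator[ChunkInterval]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def chroms(self) -> Tuple[str, ...]:
        out: List[str] = []
        for entry in self.entries:
            if not out or out[-1] != entry.chrom:
                out.append(entry.chrom)
        return tuple(out)

    def chromosome_length(self, chrom: str) -> int:
        ends = [e.end for e in self.entries if e.chrom == chrom]
        if not ends:
            raise KeyError(chrom)
        return ends[-1]

    def chunks_for(self, chrom: str) -> Tuple[ChunkInterval, ...]:
        return tuple(e for e in self.entries if e.chrom == chrom)

    def locate(self, chrom: str, pos: int) -> ChunkInterval:
        """The unique chunk containing (chrom, pos); pos == end belongs to it."""
        for entry in self.entries:
            if entry.chrom == chrom and entry.contains(pos):
                return entry
        raise KeyError(f"{chrom}:{pos} not covered by any chunk")

    def boundary_map(self) -> Dict[str, List[int]]:
        """Per-chromosome sorted chunk end positions, for bisect lookups."""
        ends: Dict[str, List[int]] = {}
        for entry in self.entries:
            ends.setdefault(entry.chrom, []).append(entry.end)
        return ends


def optimal_divisor(length: int, max_parts: int) -> int:
    """Largest n in [1, max_parts] that divides *length* exactly.

    "Fairness" of the split means every chunk has identical size, which holds
    exactly when n divides the chromosome length.  When no divisor other than
    1 exists in range (e.g. a prime length) and more than one part was
    requested, fall back to max_parts and accept an unequal final chunk.
    """
    if length < 1:
        raise ValidationError(f"length must be >= 1, got {length}")
    if max_parts < 1:
        raise ValidationError(f"max_parts must be >= 1, got {max_parts}")
    best = 1
    for n in range(min(max_parts, length), 1, -1):
        if length % n == 0:
            best = n
            break
    if best == 1 and max_parts > 1:
        return max_parts
    return best


def chunk_length_for(index: GenomeIndex, max_parts: int) -> int:
    """Chunk length from the largest chromosome and the core budget.

    L = largest chromosome length; n = optimal_divisor(L, max_parts);
    returns L/n when n divides L, else ceil(L/n) (prime-length fallback).
    """
    _, largest = largest_chromosome(index)
    n = optimal_divisor(largest, max_parts)
    return largest // n if largest % n == 0 else math.ceil(largest / n)


def build_cst(index: GenomeIndex, chunk_length: int) -> ChromosomeSplitTable:
    """Partition every chromosome into consecutive chunks of *chunk_length*.

    The k-th chunk of a chromosome of length L spans
    ``[(k-1)*chunk_length + 1, min(k*chunk_length, L)]``; numbering restarts
    at 1 per chromosome; only the final chunk may be shorter.
    """
    if chunk_length < 1:
        raise ValidationError(f"chunk_length must be >= 1, got {chunk_length}")
    entries: List[ChunkInterval] = []
    for chrom, length in index:
        n_chunks = math.ceil(length / chunk_length)
        for k in range(1, n_chunks + 1):
            start = (k - 1) * chunk_length + 1
            end = min(k * chunk_length, length)
            entries.append(ChunkInterval(chrom, k, start, end))
    return ChromosomeSplitTable(chunk_length, tuple(entries))


def write_cst(cst: ChromosomeSplitTable, path: str | os.PathLike) -> None:
    """Emit one line per chunk: ``ChrName Chunk_no Start End``."""
    with open(path, "w") as fh:
        for entry in cst:
            fh.write(f"{entry.chrom}\t{entry.chunk_no}\t{entry.start}\t{entry.end}\n")


def read_cst(path: str | os.PathLike) -> ChromosomeSplitTable:
    """Parse a 4-column CST file and validate every table invariant.

    The table's chunk length is recovered as the maximum chunk span, which
    matches the length used to build the table whenever any chromosome holds
    a full-size chunk.  Gaps, overlaps, and numbering errors raise
    :class:`ValidationError`; malformed lines raise :class:`ParseError`.
    """
    entries: List[ChunkInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
            chrom = cols[0]
            try:
                chunk_no, start, end = (int(c) for c in cols[1:])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer field in {cols[1:]}") from None
            try:
                entries.append(ChunkInterval(chrom, chunk_no, start, end))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not entries:
        raise ParseError(f"{path}: empty chromosome split table")
    chunk_length = max(e.span for e in entries)
    return ChromosomeSplitTable(chunk_length, tuple(entries))
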