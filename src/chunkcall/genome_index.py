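"""Genome coordinate frames read from FASTA index (``.fai``) files.

A :class:`GenomeIndex` is the ordered list of (chromosome, length) pairs that
every downstream stage — chunking, scatter/gather, region classification —
uses as its coordinate and sort frame.  Only the first two ``.fai`` columns
(name, length) are consumed; byte offsets and line-geometry columns written
by ``samtools faidx`` are accepted and ignored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator, Tuple

from .errors import ParseError, ValidationError

__all__ = ["GenomeIndex", "read_genome_index", "write_genome_index", "largest_chromosome"]


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths.

    Record order is preserved from the input file and defines the canonical
    chromosome sort order everywhere downstream (gather output, CST order,
    classified-region output).
    """

    records: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        seen = set()
        for name, length in self.records:
            if not name:
                raise ValidationError("empty chromosome name")
            if name in seen:
                raise ValidationError(f"duplicate chromosome name: {name!r}")
            seen.add(name)
            if not isinstance(length, int) or length < 1:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length!r}")

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(name for name, _ in self.records)

    def length_of(self, chrom: str) -> int:
        for name, length in self.records:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self.records)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.records)

    def rank(self, chrom: str) -> int:
        """Position of *chrom* in the canonical sort order (0-based)."""
        return self.names.index(chrom)


def read_genome_index(path: str | os.PathLike) -> GenomeIndex:
    """Parse a ``.fai``-dialect file: >= 2 whitespace-separated columns.

    Columns beyond (name, length) are ignored.  Raises :class:`ParseError`
    naming the offending line for empty files, duplicate names, and
    non-integer or non-positive lengths.
    """
    records: list[Tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(cols)}")
            name = cols[0]
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome name {name!r}")
            seen.add(name)
            try:
                length = int(cols[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer length {cols[1]!r}") from None
            if length < 1:
                raise ParseError(f"{path}:{lineno}: non-positive length {length}")
            records.append((name, length))
    if not records:
        raise ParseError(f"{path}: empty genome index")
    return GenomeIndex(tuple(records))


def write_genome_index(index: GenomeIndex, path: str | os.PathLike) -> None:
    """Write the two used columns (name, length), tab-separated."""
    with open(path, "w") as fh:
        for name, length in index:
            fh.write(f"{name}\t{length}\n")


def largest_chromosome(index: GenomeIndex) -> Tuple[str, int]:
    """Return the maximal-length record; ties go to the first in file order."""
    if len(index) == 0:
        raise ValidationError("empty genome index")
    best_name, best_len = index.records[0]
    for name, length in index.records[1:]:
        if length > best_len:
            best_name, best_len = name, length
    return best_name, best_len
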