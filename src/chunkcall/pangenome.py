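"""Pan-genome region and gene-group classification by occupancy.

Given per-genome presence maps on a shared focal coordinate frame, every
base is classified by the number of panel genomes whose sequence covers it
(its *occupancy* c out of N genomes):

* **core** — present in all N genomes (c == N);
* **dispensable** — present in 2..N-1 genomes;
* **specific** (private) — present in exactly one genome;
* **absent** (relative to a focal genome) — missing from the focal genome
  but present in at least one of the other N-1.

Homologous gene groups are classified with the same occupancy logic on
their membership sets.  SNPs are then counted per class by interval
containment.

Presence maps are consumed as BED (0-based half-open) on disk and held as
1-based inclusive intervals internally, matching the chunking and VCF
coordinate conventions used everywhere else in this package.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .errors import ParseError, UnknownContigError, ValidationError
from .genome_index import GenomeIndex

__all__ = [
    "PresenceMap",
    "LabeledInterval",
    "GeneGroupMembership",
    "REGION_LABELS",
    "read_presence_bed",
    "classify_regions",
    "absent_regions",
    "classify_gene_groups",
    "absent_gene_groups",
    "count_snps_by_class",
    "write_classified_bed",
    "read_bed_regions",
]

REGION_LABELS = ("core", "dispensable", "specific")

Interval = Tuple[str, int, int]  # (chrom, start, end), 1-based inclusive


@dataclass(frozen=True)
class PresenceMap:
    """Sorted disjoint 1-based inclusive intervals one genome covers."""

    genome_id: str
    intervals: Tuple[Interval, ...]

    def __post_init__(self) -> None:
        prev: Optional[Interval] = None
        for chrom, start, end in self.intervals:
            if start < 1 or end < start:
                raise ValidationError(
                    f"{self.genome_id}: bad interval {chrom}:{start}-{end}"
                )
            if prev is not None and prev[0] == chrom and start <= prev[2]:
                raise ValidationError(
                    f"{self.genome_id}: intervals overlap or are unsorted at "
                    f"{chrom}:{start}-{end}"
                )
            prev = (chrom, start, end)

    def covered_bases(self) -> int:
        return sum(end - start + 1 for _, start, end in self.intervals)


@dataclass(frozen=True)
class LabeledInterval:
    chrom: str
    start: int
    end: int
    label: str
    occupancy: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneGroupMembership:
    """A homologous gene group and the genomes holding a member of it."""

    group_id: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene group {self.group_id!r} has no members")


def read_bed_regions(path: str | os.PathLike) -> List[Interval]:
    """Read BED intervals (0-based half-open) as 1-based inclusive tuples."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], comment="#",
            names=["chrom", "start", "end"], dtype={"chrom": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: not a 3+ column BED file ({exc})") from None
    out: List[Interval] = []
    for chrom, start, end in df.itertuples(index=False):
        start, end = int(start), int(end)
        if end <= start:
            raise ParseError(f"{path}: empty or inverted BED interval {chrom}:{start}-{end}")
        out.append((chrom, start + 1, end))
    return out


def read_presence_bed(path: str | os.PathLike, genome_id: str) -> PresenceMap:
    """One genome's presence map from a BED file (sorted on read)."""
    intervals = sorted(read_bed_regions(path))
    return PresenceMap(genome_id, tuple(intervals))


def _check_frame(maps: Sequence[PresenceMap], frame: GenomeIndex) -> None:
    for pm in maps:
        for chrom, start, end in pm.intervals:
            if chrom not in frame:
                raise UnknownContigError(
                    f"{pm.genome_id}: chromosome {chrom!r} absent from the frame"
                )
            if end > frame.length_of(chrom):
                raise ValidationError(
                    f"{pm.genome_id}: interval {chrom}:{start}-{end} exceeds "
                    f"chromosome length {frame.length_of(chrom)}"
                )


def _sweep(
    chrom: str,
    length: int,
    interval_sets: Sequence[Sequence[Tuple[int, int]]],
) -> Iterable[Tuple[int, int, Tuple[int, ...]]]:
    """Fragment [1, length] at all breakpoints of the given interval sets.

    Yields (start, end, per-set coverage counts) for each fragment between
    consecutive breakpoints; counts are 0/1 per set since each set holds
    disjoint intervals.
    """
    events: Dict[int, List[int]] = {}  # position -> per-set deltas
    breakpoints: Set[int] = {1, length + 1}
    for si, ivs in enumerate(interval_sets):
        for start, end in ivs:
            breakpoints.add(start)
            breakpoints.add(end + 1)
            events.setdefault(start, [0] * len(interval_sets))[si] += 1
            events.setdefault(end + 1, [0] * len(interval_sets))[si] -= 1
    points = sorted(p for p in breakpoints if 1 <= p <= length + 1)
    counts = [0] * len(interval_sets)
    for i, p in enumerate(points[:-1]):
        if p in events:
            counts = [c + d for c, d in zip(counts, events[p])]
        yield p, points[i + 1] - 1, tuple(counts)
    # note: deltas at length+1 close the final intervals; nothing is yielded past the frame


def classify_regions(
    maps: Sequence[PresenceMap], frame: GenomeIndex
) -> List[LabeledInterval]:
    """Label every covered fragment of the frame core/dispensable/specific.

    The frame is partitioned at all presence-interval breakpoints; each
    fragment's occupancy c is the number of genomes covering it; fragments
    with c == 0 are omitted.  Adjacent fragments sharing label and occupancy
    are merged.  Output follows frame chromosome order then position.
    """
    if len(maps) < 2:
        raise ValidationError("classification needs at least 2 genomes")
    _check_frame(maps, frame)
    n = len(maps)
    per_chrom: Dict[str, List[List[Tuple[int, int]]]] = {
        chrom: [[] for _ in maps] for chrom, _ in frame
    }
    for mi, pm in enumerate(maps):
        for chrom, start, end in pm.intervals:
            per_chrom[chrom][mi].append((start, end))

    out: List[LabeledInterval] = []
    for chrom, length in frame:
        for start, end, counts in _sweep(chrom, length, per_chrom[chrom]):
            c = sum(counts)
            if c == 0:
                continue
            if c == n:
                label = "core"
            elif c == 1:
                label = "specific"
            else:
                label = "dispensable"
            if (
                out
                and out[-1].chrom == chrom
                and out[-1].end + 1 == start
                and out[-1].label == label
                and out[-1].occupancy == c
            ):
                out[-1] = LabeledInterval(chrom, out[-1].start, end, label, c)
            else:
                out.append(LabeledInterval(chrom, start, end, label, c))
    return out


def absent_regions(
    maps: Sequence[PresenceMap], frame: GenomeIndex, focal: str
) -> List[Interval]:
    """Fragments not covered by *focal* but covered by >= 1 other genome."""
    ids = [pm.genome_id for pm in maps]
    if focal not in ids:
        raise ValidationError(f"unknown focal genome {focal!r} (panel: {ids})")
    _check_frame(maps, frame)
    focal_idx = ids.index(focal)

    out: List[Interval] = []
    for chrom, length in frame:
        sets: List[List[Tuple[int, int]]] = [[] for _ in maps]
        for mi, pm in enumerate(maps):
            for c, s, e in pm.intervals:
                if c == chrom:
                    sets[mi].append((s, e))
        for start, end, counts in _sweep(chrom, length, sets):
            others = sum(counts) - counts[focal_idx]
            if counts[focal_idx] == 0 and others >= 1:
                if out and out[-1][0] == chrom and out[-1][2] + 1 == start:
                    out[-1] = (chrom, out[-1][1], end)
                else:
                    out.append((chrom, start, end))
    return out


def classify_gene_groups(
    groups: Sequence[GeneGroupMembership], panel: Sequence[str]
) -> Dict[str, str]:
    """Core/dispensable/private label per homologous gene group.

    core iff a member is present in every panel genome; private (specific)
    iff in exactly one; dispensable otherwise.
    """
    panel_set = set(panel)
    n = len(panel_set)
    if n < 2:
        raise ValidationError("gene-group classification needs a panel of >= 2 genomes")
    out: Dict[str, str] = {}
    for g in groups:
        extra = set(g.members) - panel_set
        if extra:
            raise ValidationError(
                f"gene group {g.group_id!r} has members outside the panel: {sorted(extra)}"
            )
        k = len(g.members)
        out[g.group_id] = "core" if k == n else ("private" if k == 1 else "dispensable")
    return out


def absent_gene_groups(
    groups: Sequence[GeneGroupMembership], panel: Sequence[str], focal: str
) -> List[str]:
    """Groups present in all panel genomes except the focal one
    (|members| == N-1 and focal not a member)."""
    panel_set = set(panel)
    if focal not in panel_set:
        raise ValidationError(f"unknown focal genome {focal!r}")
    n = len(panel_set)
    return [
        g.group_id
        for g in groups
        if len(g.members) == n - 1 and focal not in g.members
    ]


def count_snps_by_class(
    variants: Iterable[Tuple[str, int]],
    labeled_intervals: Sequence[LabeledInterval],
) -> Counter:
    """Count variants per region class by interval containment.

    *variants* is an iterable of (chrom, 1-based pos).  A variant outside
    every labeled fragment is counted under ``"unclassified"``.
    """
    trees: Dict[str, IntervalTree] = {}
    for li in labeled_intervals:
        trees.setdefault(li.chrom, IntervalTree()).addi(li.start, li.end + 1, li.label)
    counts: Counter = Counter()
    for chrom, pos in variants:
        tree = trees.get(chrom)
        hits = tree[pos] if tree is not None else ()
        if hits:
            # labeled fragments are disjoint, so at most one hit
            counts[next(iter(hits)).data] += 1
        else:
            counts["unclassified"] += 1
    return counts


def write_classified_bed(
    labeled_intervals: Sequence[LabeledInterval], path: str | os.PathLike
) -> None:
    """BED out: chrom, 0-based start, end, label, occupancy."""
    with open(path, "w") as fh:
        for li in labeled_intervals:
            fh.write(f"{li.chrom}\t{li.start - 1}\t{li.end}\t{li.label}\t{li.occupancy}\n")
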