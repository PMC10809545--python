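"""Shared pysam VCF header/record helpers.

Centralises the header boilerplate (contig lines from a GenomeIndex, the six
filterable annotation definitions, GT) so the combiner, gather/split, filter
and fixture modules all emit mutually compatible VCFs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pysam

from .genome_index import GenomeIndex

#: INFO definitions for the annotations the hard filter reads (QUAL lives in
#: the fixed QUAL column).  DP is an integer depth; the rest are floats.
ANNOTATION_INFO_LINES = (
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum z-score">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum z-score">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined read depth">',
)

FORMAT_GT_LINE = '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'


def build_header(
    frame: GenomeIndex | Iterable[tuple[str, int]],
    samples: Sequence[str] = (),
    annotation_info: bool = True,
) -> pysam.VariantHeader:
    """A VCF header with contigs from *frame*, GT, and optionally the six
    filterable annotation INFO lines."""
    header = pysam.VariantHeader()
    for name, length in frame:
        header.contigs.add(name, length=length)
    if annotation_info:
        for line in ANNOTATION_INFO_LINES:
            header.add_line(line)
    header.add_line(FORMAT_GT_LINE)
    for sample in samples:
        header.add_sample(sample)
    return header


def copy_header(src: pysam.VariantHeader) -> pysam.VariantHeader:
    """An independent copy of *src* (pysam headers are mutable in place)."""
    return src.copy()


def record_key(rec: pysam.VariantRecord) -> tuple[str, int, str, tuple[str, ...]]:
    """Identity of a site for duplicate detection: (chrom, pos, ref, alts)."""
    return (rec.chrom, rec.pos, rec.ref or "", tuple(rec.alts or ()))


def samples_of(vf: pysam.VariantFile) -> tuple[str, ...]:
    return tuple(vf.header.samples)
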