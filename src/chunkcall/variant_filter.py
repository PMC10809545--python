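"""SNP selection and hard filtering of joint-genotype call sets.

Sites are retained as SNPs when both REF and every ALT allele are single
nucleotides; mixed SNP/indel sites are dropped whole.  Retained sites are
then judged against a disjunction of six fixed annotation cutoffs

    QUAL < 30.0 || QD < 2.0 || MQ < 20.0 || MQRankSum < -3.0
        || ReadPosRankSum < -3.0 || DP < 5.0

— a site fails the filter as soon as any one annotation falls strictly below
its cutoff.  By default an absent annotation never fails its condition (the
conventional treatment of missing annotations in hard filtering); pass
``missing_fails=True`` to invert that.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields
from typing import Iterable, Iterator, Optional, Tuple

import pysam

from ._vcfio import copy_header
from .errors import ParseError, ValidationError

__all__ = [
    "SiteAnnotations",
    "FilterThresholds",
    "FilterVerdict",
    "DEFAULT_THRESHOLDS",
    "REASON_CODES",
    "is_snp_site",
    "select_snps",
    "hard_filter",
    "annotations_from_record",
    "apply_filters",
    "filter_vcf",
]

_SNP_BASES = frozenset("ACGT")

#: Fixed reporting order of failed-condition codes.
REASON_CODES = ("QUAL", "QD", "MQ", "MQRankSum", "ReadPosRankSum", "DP")

# (reason code, SiteAnnotations/FilterThresholds field name)
_CONDITIONS = (
    ("QUAL", "qual"),
    ("QD", "qd"),
    ("MQ", "mq"),
    ("MQRankSum", "mq_rank_sum"),
    ("ReadPosRankSum", "read_pos_rank_sum"),
    ("DP", "dp"),
)


@dataclass(frozen=True)
class SiteAnnotations:
    """The six filterable annotations of one site; ``None`` means absent."""

    qual: Optional[float] = None
    qd: Optional[float] = None
    mq: Optional[float] = None
    mq_rank_sum: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None
    dp: Optional[float] = None

    def __post_init__(self) -> None:
        import math

        for f in fields(self):
            value = getattr(self, f.name)
            if value is not None and not math.isfinite(value):
                raise ValidationError(f"non-finite annotation {f.name}={value!r}")


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs of the hard-filter disjunction; defaults are the standard
    high-quality-SNP settings this package ships with."""

    qual: float = 30.0
    qd: float = 2.0
    mq: float = 20.0
    mq_rank_sum: float = -3.0
    read_pos_rank_sum: float = -3.0
    dp: float = 5.0


DEFAULT_THRESHOLDS = FilterThresholds()


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reasons: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValidationError("verdict inconsistent: passed must equal 'no reasons'")


def is_snp_site(ref: Optional[str], alts: Iterable[str]) -> bool:
    """True iff REF is one base and every ALT is one of A/C/G/T.

    Sites with no ALT allele at all (reference-only records) are not SNPs;
    symbolic (<DEL>, <NON_REF>), breakend, and indel alleles disqualify the
    whole site.
    """
    if ref is None or len(ref) != 1 or ref.upper() not in _SNP_BASES:
        return False
    alts = tuple(alts)
    if not alts:
        return False
    return all(a is not None and len(a) == 1 and a.upper() in _SNP_BASES for a in alts)


def select_snps(records: Iterable[pysam.VariantRecord]) -> Iterator[pysam.VariantRecord]:
    """Yield only pure-SNP sites (multiallelic all-SNP sites included)."""
    for rec in records:
        if is_snp_site(rec.ref, rec.alts or ()):
            yield rec


def hard_filter(
    ann: SiteAnnotations,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    missing_fails: bool = False,
) -> FilterVerdict:
    """Evaluate the six-condition disjunction on one site.

    A condition fails iff its annotation is present and strictly below its
    cutoff; with ``missing_fails`` an absent annotation also fails.  The
    verdict fails iff any condition fails, reasons reported in fixed order.
    """
    reasons = []
    for code, name in _CONDITIONS:
        value = getattr(ann, name)
        if value is None:
            if missing_fails:
                reasons.append(code)
        elif value < getattr(thresholds, name):
            reasons.append(code)
    return FilterVerdict(passed=not reasons, reasons=tuple(reasons))


def _as_float(value: object, site: str, key: str) -> float:
    if isinstance(value, tuple):  # Number mismatch in the header: take first
        value = value[0]
    try:
        return float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ParseError(f"{site}: annotation {key}={value!r} is not numeric") from None


def annotations_from_record(rec: pysam.VariantRecord) -> SiteAnnotations:
    """Pull QUAL and the INFO keys QD/MQ/MQRankSum/ReadPosRankSum/DP.

    Malformed (non-numeric) annotation values raise :class:`ParseError`
    naming the site.
    """
    site = f"{rec.chrom}:{rec.pos}"
    info = rec.info
    values: dict[str, Optional[float]] = {"qual": rec.qual if rec.qual is not None else None}
    for code, name in _CONDITIONS[1:]:
        raw = info.get(code)
        values[name] = None if raw is None else _as_float(raw, site, code)
    return SiteAnnotations(**values)


def apply_filters(
    records: Iterable[pysam.VariantRecord],
    emit: str = "flag",
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    missing_fails: bool = False,
) -> Iterator[Tuple[pysam.VariantRecord, FilterVerdict]]:
    """Judge each record, preserving order.

    ``emit='flag'`` yields every record with its verdict (the caller writes
    FILTER); ``emit='pass_only'`` yields passing records only.
    """
    if emit not in ("flag", "pass_only"):
        raise ValidationError(f"emit must be 'flag' or 'pass_only', got {emit!r}")
    for rec in records:
        verdict = hard_filter(annotations_from_record(rec), thresholds, missing_fails)
        if emit == "flag" or verdict.passed:
            yield rec, verdict


def filter_vcf(
    in_path: str | os.PathLike,
    out_path: str | os.PathLike,
    emit: str = "flag",
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    missing_fails: bool = False,
    snps_only: bool = False,
) -> Tuple[int, int]:
    """Filter a VCF file; returns (records written, records failing).

    Flag mode writes all input records with FILTER set to ``PASS`` or the
    semicolon-joined reason codes; pass-only mode writes passing records
    with FILTER ``PASS``.  ``snps_only`` additionally restricts the stream
    to pure-SNP sites first.
    """
    if emit not in ("flag", "pass_only"):
        raise ValidationError(f"emit must be 'flag' or 'pass_only', got {emit!r}")
    n_out = n_fail = 0
    with pysam.VariantFile(os.fspath(in_path)) as vin:
        header = copy_header(vin.header)
        for code in REASON_CODES:
            if code not in header.filters:
                header.add_line(
                    f'##FILTER=<ID={code},Description="Hard-filter condition {code} failed">'
                )
        with pysam.VariantFile(os.fspath(out_path), "w", header=header) as vout:
            stream: Iterable[pysam.VariantRecord] = vin
            if snps_only:
                stream = select_snps(stream)
            for rec, verdict in apply_filters(stream, "flag", thresholds, missing_fails):
                if not verdict.passed:
                    n_fail += 1
                    if emit == "pass_only":
                        continue
                rec.translate(header)
                out = rec
                out.filter.clear()
                if verdict.passed:
                    out.filter.add("PASS")
                else:
                    for code in verdict.reasons:
                        out.filter.add(code)
                vout.write(out)
                n_out += 1
    return n_out, n_fail
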