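"""Population-level SNP summaries over a sites x samples genotype matrix.

Covers the per-site statistics used to validate and interpret a pan-genome
call set: minor allele frequency (MAF), accession support (how many samples
carry a non-reference allele), support-threshold validation of putative
novel SNPs, presence/allele-status summaries at a diagnostic site of a
presence/absence-variable gene, intersection of SNPs with open chromatin
regions (OCR peak BEDs), and percentile-tail selection from a variant
score table.

Conventions (documented, since tools differ): allele frequencies are taken
over non-missing *called alleles* (two per diploid call, one per haploid
call); accession support counts carriers per sample, not per allele, so a
homozygous-alternate sample counts once; percentages are reported to two
decimals with half-up rounding.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .errors import ValidationError

__all__ = [
    "Site",
    "GenotypeMatrix",
    "AlleleStatusSummary",
    "minor_allele_frequency",
    "accession_support",
    "support_validation",
    "allele_status_summary",
    "snps_in_regions",
    "percentile_tails",
    "read_score_table",
]

#: sentinel allele codes in GenotypeMatrix.calls
MISSING = -1  # './.' style missing allele
NO_SLOT = -2  # absent second slot of a haploid call


@dataclass(frozen=True)
class Site:
    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]


@dataclass
class GenotypeMatrix:
    """Diploid (or haploid) calls for sites x samples.

    ``calls`` has shape (n_sites, n_samples, 2) with allele indexes
    (0 = REF, 1.. = ALTs), ``MISSING`` for uncalled alleles and ``NO_SLOT``
    for the unused slot of a haploid call.
    """

    sites: List[Site]
    samples: List[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(self.sites), len(self.samples), 2)
        if self.calls.shape != expected:
            raise ValidationError(
                f"calls shape {self.calls.shape} != (sites, samples, 2) {expected}"
            )
        for i, site in enumerate(self.sites):
            top = self.calls[i].max(initial=MISSING)
            if top > len(site.alts):
                raise ValidationError(
                    f"site {site.chrom}:{site.pos}: allele index {top} out of range "
                    f"for {len(site.alts)} ALT allele(s)"
                )

    @classmethod
    def from_vcf(cls, path: str | os.PathLike) -> "GenotypeMatrix":
        """Load every site of a multi-sample VCF (cyvcf2-backed)."""
        from cyvcf2 import VCF

        vcf = VCF(os.fspath(path), gts012=False)
        samples = list(vcf.samples)
        sites: List[Site] = []
        rows: List[np.ndarray] = []
        for v in vcf:
            sites.append(Site(v.CHROM, v.POS, v.REF, tuple(v.ALT)))
            row = np.full((len(samples), 2), NO_SLOT, dtype=np.int16)
            for si, gt in enumerate(v.genotypes):
                alleles = gt[:-1]  # last element is the phased flag
                for ai, a in enumerate(alleles[:2]):
                    row[si, ai] = MISSING if a < 0 else a
            rows.append(row)
        vcf.close()
        calls = (
            np.stack(rows) if rows else np.empty((0, len(samples), 2), dtype=np.int16)
        )
        return cls(sites, samples, calls)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def minor_allele_frequency(matrix: GenotypeMatrix, site_index: int) -> Optional[float]:
    """MAF = frequency of the second-most-common allele at the site.

    Frequencies are over non-missing called alleles; monomorphic sites give
    0.0; a site with every call missing has no defined MAF and returns
    ``None``.  Always in [0, 0.5].
    """
    alleles = matrix.calls[site_index].ravel()
    alleles = alleles[alleles >= 0]
    if alleles.size == 0:
        return None
    counts = np.bincount(alleles)
    if (counts > 0).sum() < 2:
        return 0.0
    top2 = np.sort(counts)[-2:]
    return float(top2[0] / alleles.size)


def accession_support(matrix: GenotypeMatrix, site_index: int) -> int:
    """Number of samples carrying >= 1 non-reference allele at the site.

    Missing calls contribute nothing; a homozygous-alternate sample counts
    once (support is per accession, not per allele).
    """
    return int((matrix.calls[site_index] >= 1).any(axis=1).sum())


def support_validation(
    matrix: GenotypeMatrix,
    site_indices: Optional[Sequence[int]] = None,
    min_support: int = 3,
) -> Tuple[int, float]:
    """How many sites are carried by >= *min_support* accessions.

    Returns (n_validated, fraction of the site list).  This is the check
    used to corroborate putative novel SNPs against a large resequencing
    panel: a site seen independently in several accessions is unlikely to
    be a calling artifact.
    """
    if min_support < 1:
        raise ValidationError(f"min_support must be >= 1, got {min_support}")
    indices = range(matrix.n_sites) if site_indices is None else site_indices
    indices = list(indices)
    if not indices:
        raise ValidationError("empty site list")
    n_validated = sum(
        1 for i in indices if accession_support(matrix, i) >= min_support
    )
    return n_validated, n_validated / len(indices)


def _pct2(count: int, total: int) -> float:
    """count/total as a percentage, two decimals, half-up."""
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class AlleleStatusSummary:
    """Presence/allele status of a gene across a panel of accessions.

    ``counts`` maps ``"absent"`` plus each allele label to accession counts;
    ``percentages`` expresses each over *all* accessions (present + absent).
    """

    n_total: int
    n_absent: int
    counts: Mapping[str, int]
    percentages: Mapping[str, float]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_total:
            raise ValidationError("allele-status counts do not sum to n_total")


def allele_status_summary(
    presence: Mapping[str, bool],
    allele_calls: Mapping[str, str],
) -> AlleleStatusSummary:
    """Summarise gene presence and allele status across accessions.

    *presence* flags whether each accession carries the gene at all;
    *allele_calls* labels the allele of every gene-present accession at a
    diagnostic site.  An allele label on a gene-absent accession, or a
    gene-present accession without a label, is an error.
    """
    counts: Dict[str, int] = {"absent": 0}
    for acc, present in presence.items():
        if not present:
            if acc in allele_calls:
                raise ValidationError(
                    f"accession {acc!r} is gene-absent but has an allele label"
                )
            counts["absent"] += 1
        else:
            label = allele_calls.get(acc)
            if label is None:
                raise ValidationError(
                    f"gene-present accession {acc!r} lacks an allele label"
                )
            counts[label] = counts.get(label, 0) + 1
    extra = set(allele_calls) - set(presence)
    if extra:
        raise ValidationError(f"allele labels for unknown accessions: {sorted(extra)}")
    n_total = len(presence)
    if n_total == 0:
        raise ValidationError("no accessions supplied")
    percentages = {k: _pct2(v, n_total) for k, v in counts.items()}
    return AlleleStatusSummary(n_total, counts["absent"], counts, percentages)


def snps_in_regions(
    variants: Iterable[Tuple[str, int]],
    regions: Sequence[Tuple[str, int, int]],
) -> Tuple[List[Tuple[str, int]], int]:
    """Variants whose 1-based position lies inside any region.

    *regions* are 1-based inclusive (chrom, start, end) — use
    :func:`chunkcall.pangenome.read_bed_regions` to convert a peak BED.
    Returns (subset in input order, count).
    """
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
    subset = [
        (chrom, pos)
        for chrom, pos in variants
        if chrom in trees and trees[chrom].overlaps(pos)
    ]
    return subset, len(subset)


def percentile_tails(
    entries: Sequence[Tuple[str, float]],
    tail_fraction: float = 0.05,
) -> List[str]:
    """Site ids in the top and bottom *tail_fraction* of scores.

    Nearest-rank selection: k = ceil(tail_fraction * n) entries from each
    end of the score ordering, ties at the cut broken by site_id so the
    selection is deterministic.  Returns the union (a single site can sit
    in both tails only when n is tiny), sorted by site_id.
    """
    if not entries:
        raise ValidationError("empty score table")
    if not (0 < tail_fraction < 0.5):
        raise ValidationError(
            f"tail_fraction must be in (0, 0.5), got {tail_fraction}"
        )
    for site_id, score in entries:
        if not math.isfinite(score):
            raise ValidationError(f"non-finite score for {site_id!r}")
    n = len(entries)
    k = math.ceil(tail_fraction * n)
    bottom = sorted(entries, key=lambda e: (e[1], e[0]))[:k]
    top = sorted(entries, key=lambda e: (-e[1], e[0]))[:k]
    return sorted({site_id for site_id, _ in bottom} | {site_id for site_id, _ in top})


def read_score_table(path: str | os.PathLike) -> List[Tuple[str, float]]:
    """Two-column (site_id, score) TSV -> entry list."""
    import pandas as pd

    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1], names=["site_id", "score"],
        dtype={"site_id": str, "score": float}, comment="#",
    )
    return list(df.itertuples(index=False, name=None))
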