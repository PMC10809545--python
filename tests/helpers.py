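"""Small VCF-writing helpers shared by the test modules."""

from __future__ import annotations

from typing import Mapping, Sequence, Tuple

import pysam

from chunkcall._vcfio import build_header


def write_vcf(
    path,
    contigs: Sequence[Tuple[str, int]],
    samples: Sequence[str],
    records: Sequence[dict],
) -> str:
    """Write a small VCF from record dicts.

    Each record: chrom, pos (1-based), ref, alts (tuple), and optionally
    qual, info (mapping), gts (mapping sample -> allele-index tuple).
    """
    header = build_header(contigs, samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for spec in records:
            rec = out.new_record(
                contig=spec["chrom"],
                start=spec["pos"] - 1,
                stop=spec["pos"] - 1 + len(spec["ref"]),
                alleles=(spec["ref"], *spec["alts"]),
            )
            if "qual" in spec:
                rec.qual = spec["qual"]
            for key, value in spec.get("info", {}).items():
                rec.info[key] = value
            gts: Mapping = spec.get("gts", {})
            for i, sample in enumerate(samples):
                rec.samples[i]["GT"] = gts.get(sample, (None, None))
            out.write(rec)
    return str(path)


def record_stream(path) -> list:
    """Comparable (chrom, pos, ref, alts, genotypes) tuples of a VCF."""
    with pysam.VariantFile(str(path)) as vf:
        return [
            (
                rec.chrom,
                rec.pos,
                rec.ref,
                rec.alts,
                tuple(tuple(rec.samples[s]["GT"]) for s in rec.samples),
            )
            for rec in vf
        ]
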