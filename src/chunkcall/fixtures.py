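"""Seeded synthetic data: genome indexes, variant cohorts, presence maps.

Every generator is deterministic for a fixed seed and records the ground
truth it plants (site annotations and their expected hard-filter verdicts,
per-class base totals of presence maps, per-site carrier counts), so the
analysis modules can be tested by exact recovery with no external data.

One integer seed drives one named pseudo-random stream per generator
(seed + CRC32 of the generator name), so adding a generator never perturbs
the fixtures an existing one emits.

The cohort generator emulates the per-sample output of an upstream variant
caller: SNP sites scattered uniformly over the frame, site annotations
drawn from simple parametric distributions chosen so that roughly 10-30% of
sites fail each hard-filter condition (both filter branches are exercised),
and a random subset of samples carrying each site.  It does not emulate
read-level error processes, linkage, population structure, or gVCF
reference blocks.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from ._vcfio import build_header
from .errors import ValidationError
from .genome_index import GenomeIndex, write_genome_index
from .pangenome import LabeledInterval, PresenceMap
from .variant_filter import DEFAULT_THRESHOLDS, FilterThresholds

__all__ = [
    "AnnotationModel",
    "CohortFixture",
    "PresenceFixture",
    "synth_genome_index",
    "synth_cohort",
    "synth_presence_maps",
    "synth_validation_manifest",
]

_BASES = np.array(list("ACGT"))


def _rng(seed: int, stream: str) -> np.random.Generator:
    """One independent, reproducible stream per (seed, generator name)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


def synth_genome_index(
    seed: int,
    n_chrom: int = 12,
    min_len: int = 20_000_000,
    max_len: int = 45_000_000,
    path: Optional[str | os.PathLike] = None,
) -> GenomeIndex:
    """A synthetic genome index named Chr01..ChrNN.

    Defaults emulate a rice-like nuclear genome: 12 chromosomes of 20-45 Mb.
    Lengths are uniform in [min_len, max_len]; the index is written to
    *path* (two-column ``.fai`` dialect) when given.
    """
    if n_chrom < 1:
        raise ValidationError(f"n_chrom must be >= 1, got {n_chrom}")
    if not (1 <= min_len <= max_len):
        raise ValidationError(f"need 1 <= min_len <= max_len, got {min_len}, {max_len}")
    rng = _rng(seed, "genome_index")
    lengths = rng.integers(min_len, max_len + 1, size=n_chrom)
    index = GenomeIndex(
        tuple((f"Chr{i:02d}", int(L)) for i, L in enumerate(lengths, start=1))
    )
    if path is not None:
        write_genome_index(index, path)
    return index


@dataclass(frozen=True)
class AnnotationModel:
    """Distributions for the six filterable site annotations.

    Defaults put each hard-filter condition's failure mass in the 10-30%
    band under the standard cutoffs:

    * QUAL ~ offset + Exponential(scale): P(QUAL < 30) ~= 18%
    * QD   ~ Normal(mean, sd) clipped at 0: P(QD < 2) ~= 16%
    * MQ   ~ Normal(mean, sd) clipped at 0: P(MQ < 20) ~= 16%
    * rank-sums ~ Normal(0, sd): P(< -3) ~= 12%
    * DP   ~ Poisson(mean): P(DP < 5) ~= 17%
    """

    qual_offset: float = 20.0
    qual_scale: float = 50.0
    qd_mean: float = 10.0
    qd_sd: float = 8.0
    mq_mean: float = 30.0
    mq_sd: float = 10.0
    ranksum_sd: float = 2.5
    dp_mean: float = 7.0

    def draw(self, rng: np.random.Generator, n: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "qual": self.qual_offset + rng.exponential(self.qual_scale, n),
                "qd": np.clip(rng.normal(self.qd_mean, self.qd_sd, n), 0.0, None),
                "mq": np.clip(rng.normal(self.mq_mean, self.mq_sd, n), 0.0, None),
                "mq_rank_sum": rng.normal(0.0, self.ranksum_sd, n),
                "read_pos_rank_sum": rng.normal(0.0, self.ranksum_sd, n),
                "dp": rng.poisson(self.dp_mean, n),
            }
        )


@dataclass(frozen=True)
class CohortFixture:
    """Emitted cohort files plus the planted ground truth."""

    frame: GenomeIndex
    sample_names: Tuple[str, ...]
    sample_paths: Tuple[str, ...]
    joint_path: str
    truth: pd.DataFrame  # one row per site, includes expected verdicts
    truth_path: str


def _expected_reasons(row: pd.Series, t: FilterThresholds) -> List[str]:
    # independent spelled-out comparisons, mirrored by tests against the
    # filter module's verdicts
    reasons = []
    if row["qual"] < t.qual:
        reasons.append("QUAL")
    if row["qd"] < t.qd:
        reasons.append("QD")
    if row["mq"] < t.mq:
        reasons.append("MQ")
    if row["mq_rank_sum"] < t.mq_rank_sum:
        reasons.append("MQRankSum")
    if row["read_pos_rank_sum"] < t.read_pos_rank_sum:
        reasons.append("ReadPosRankSum")
    if row["dp"] < t.dp:
        reasons.append("DP")
    return reasons


def _unique_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions, uniform over [1, length]."""
    if n >= length:
        return np.arange(1, length + 1)
    chosen: set = set()
    while len(chosen) < n:
        draw = rng.integers(1, length + 1, size=n - len(chosen))
        chosen.update(int(p) for p in draw)
        # trim any overshoot deterministically
        if len(chosen) > n:
            chosen = set(sorted(chosen)[:n])
    return np.array(sorted(chosen))


def synth_cohort(
    seed: int,
    frame: GenomeIndex,
    n_samples: int,
    outdir: str | os.PathLike,
    snp_rate: float = 1e-4,
    model: AnnotationModel = AnnotationModel(),
    carrier_prob: float = 0.5,
    hom_prob: float = 0.3,
) -> CohortFixture:
    """Per-sample VCFs, a joint multi-sample VCF, and the planted truth.

    Per chromosome of length L, Binomial(L, snp_rate) SNP sites are placed
    uniformly at distinct positions.  Each site carries one set of planted
    annotations (written identically into every carrier's record and the
    joint file) and is carried by a random subset of samples (each with
    probability *carrier_prob*, at least one forced), heterozygous or
    homozygous-alternate.  The truth table records the annotations, the
    expected hard-filter verdict under the default cutoffs, and the carrier
    count per site.
    """
    if n_samples < 1:
        raise ValidationError(f"n_samples must be >= 1, got {n_samples}")
    if not (0 <= snp_rate <= 0.01):
        raise ValidationError(f"snp_rate must be in [0, 0.01], got {snp_rate}")
    rng = _rng(seed, "cohort")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_names = tuple(f"S{i:03d}" for i in range(1, n_samples + 1))

    rows: List[dict] = []
    for chrom, length in frame:
        n_sites = int(rng.binomial(length, snp_rate)) if snp_rate > 0 else 0
        positions = _unique_positions(rng, length, n_sites)
        for pos in positions:
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            rows.append({"chrom": chrom, "pos": int(pos), "ref": str(ref), "alt": str(alt)})
    truth = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt"]
    )

    ann = model.draw(rng, len(truth))
    truth = pd.concat([truth.reset_index(drop=True), ann], axis=1)
    reasons = [
        _expected_reasons(row, DEFAULT_THRESHOLDS) for _, row in truth.iterrows()
    ]
    truth["filter_pass"] = [not r for r in reasons]
    truth["fail_reasons"] = [";".join(r) for r in reasons]

    # carriers: sample x site boolean, each column forced non-empty
    n_sites_total = len(truth)
    carriers = rng.random((n_sites_total, n_samples)) < carrier_prob
    for i in range(n_sites_total):
        if not carriers[i].any():
            carriers[i, rng.integers(n_samples)] = True
    hom = rng.random((n_sites_total, n_samples)) < hom_prob
    truth["n_carriers"] = carriers.sum(axis=1).astype(int)

    def _write_vcf(path: Path, sample_subset: Sequence[int]) -> None:
        header = build_header(frame, [sample_names[i] for i in sample_subset])
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for i, row in truth.iterrows():
                row_carriers = [s for s in sample_subset if carriers[i, s]]
                if len(sample_subset) == 1 and not row_carriers:
                    continue  # per-sample file: omit sites the sample lacks
                rec = out.new_record(
                    contig=row["chrom"],
                    start=row["pos"] - 1,
                    stop=row["pos"],
                    alleles=(row["ref"], row["alt"]),
                )
                rec.qual = float(row["qual"])
                rec.info["QD"] = float(row["qd"])
                rec.info["MQ"] = float(row["mq"])
                rec.info["MQRankSum"] = float(row["mq_rank_sum"])
                rec.info["ReadPosRankSum"] = float(row["read_pos_rank_sum"])
                rec.info["DP"] = int(row["dp"])
                for col, s in enumerate(sample_subset):
                    if carriers[i, s]:
                        rec.samples[col]["GT"] = (1, 1) if hom[i, s] else (0, 1)
                    elif len(sample_subset) > 1:
                        rec.samples[col]["GT"] = (None, None)
                out.write(rec)

    sample_paths = []
    for s, name in enumerate(sample_names):
        path = outdir / f"{name}.vcf"
        _write_vcf(path, [s])
        sample_paths.append(str(path))
    joint_path = outdir / "joint.vcf"
    _write_vcf(joint_path, list(range(n_samples)))

    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return CohortFixture(
        frame, sample_names, tuple(sample_paths), str(joint_path), truth, str(truth_path)
    )


@dataclass(frozen=True)
class PresenceFixture:
    """Planted presence maps and the exact per-class ground truth."""

    maps: Tuple[PresenceMap, ...]
    truth_intervals: Tuple[LabeledInterval, ...]
    base_totals: Dict[str, int]  # label -> planted bases (core/dispensable/specific)
    bed_paths: Tuple[str, ...] = ()


def synth_presence_maps(
    seed: int,
    frame: GenomeIndex,
    n_genomes: int,
    fractions: Tuple[float, float, float] = (0.80, 0.15, 0.04),
    n_blocks: int = 40,
    outdir: Optional[str | os.PathLike] = None,
) -> PresenceFixture:
    """Presence maps whose per-base classes hit the target fractions exactly.

    *fractions* are the (core, dispensable, specific) shares of the frame's
    total bases; the remainder is left uncovered.  The frame is linearised,
    the exact per-class base totals are split into ~*n_blocks* blocks,
    shuffled, and laid down contiguously; each block is assigned to all
    genomes (core), a random 2..N-1 subset (dispensable), one genome
    (specific), or none.  The defaults mirror a crop pan-genome where ~80%
    of sequence is shared by every genome.  Running the region classifier
    on the emitted maps recovers ``base_totals`` exactly by construction.
    """
    if n_genomes < 2:
        raise ValidationError("presence fixtures need >= 2 genomes")
    if any(f < 0 for f in fractions) or sum(fractions) > 1.0 + 1e-12:
        raise ValidationError(f"infeasible class fractions {fractions}")
    if n_genomes == 2 and fractions[1] > 0:
        raise ValidationError(
            "dispensable regions (occupancy 2..N-1) are infeasible with N=2 genomes"
        )
    rng = _rng(seed, "presence_maps")
    total = frame.total_length
    targets = {
        "core": int(round(fractions[0] * total)),
        "dispensable": int(round(fractions[1] * total)),
        "specific": int(round(fractions[2] * total)),
    }
    if sum(targets.values()) > total:
        raise ValidationError(f"rounded class targets exceed the frame ({targets})")
    targets["none"] = total - sum(targets.values())

    # split each class total into blocks, then shuffle the block order
    blocks: List[Tuple[str, int]] = []
    for label, bases in targets.items():
        remaining = bases
        share = max(1, n_blocks // 4)
        approx = max(1, bases // share) if bases else 0
        while remaining > 0:
            size = min(remaining, approx)
            blocks.append((label, size))
            remaining -= size
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    genome_ids = tuple(f"G{i:02d}" for i in range(1, n_genomes + 1))
    per_genome: Dict[str, List[Tuple[str, int, int]]] = {g: [] for g in genome_ids}
    truth: List[LabeledInterval] = []

    chrom_iter = iter(frame)
    chrom, chrom_len = next(chrom_iter)
    cursor = 1  # 1-based position within the current chromosome

    def _assign(label: str, start: int, end: int, chrom: str) -> None:
        if label == "none":
            return
        if label == "core":
            chosen = genome_ids
            occ = n_genomes
        elif label == "specific":
            chosen = (genome_ids[rng.integers(n_genomes)],)
            occ = 1
        else:
            occ = int(rng.integers(2, n_genomes))  # 2..N-1
            chosen = tuple(
                genome_ids[i] for i in rng.choice(n_genomes, size=occ, replace=False)
            )
        for g in chosen:
            ivs = per_genome[g]
            if ivs and ivs[-1][0] == chrom and ivs[-1][2] + 1 == start:
                ivs[-1] = (chrom, ivs[-1][1], end)
            else:
                ivs.append((chrom, start, end))
        if truth and truth[-1].chrom == chrom and truth[-1].end + 1 == start \
                and truth[-1].label == label and truth[-1].occupancy == occ:
            truth[-1] = LabeledInterval(chrom, truth[-1].start, end, label, occ)
        else:
            truth.append(LabeledInterval(chrom, start, end, label, occ))

    for label, size in blocks:
        while size > 0:
            take = min(size, chrom_len - cursor + 1)
            _assign(label, cursor, cursor + take - 1, chrom)
            cursor += take
            size -= take
            if cursor > chrom_len and size >= 0:
                nxt = next(chrom_iter, None)
                if nxt is None:
                    if size > 0:
                        raise ValidationError("block layout overran the frame")
                    break
                chrom, chrom_len = nxt
                cursor = 1

    maps = tuple(
        PresenceMap(g, tuple(sorted(per_genome[g], key=lambda iv: (frame.rank(iv[0]), iv[1]))))
        for g in genome_ids
    )
    bed_paths: Tuple[str, ...] = ()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for pm in maps:
            path = outdir / f"{pm.genome_id}.bed"
            with open(path, "w") as fh:
                for c, s, e in pm.intervals:
                    fh.write(f"{c}\t{s - 1}\t{e}\n")
            paths.append(str(path))
        bed_paths = tuple(paths)
    base_totals = {k: v for k, v in targets.items() if k != "none"}
    return PresenceFixture(maps, tuple(truth), base_totals, bed_paths)


def synth_validation_manifest(
    n_insertions: int,
    n_deletions: int,
    n_queries: int,
    seed: int = 0,
) -> pd.DataFrame:
    """A structural-variant validation manifest: one row per (SV, query).

    Emulates sampling insertions and deletions against a reference and
    checking each against every query genome; the row count is
    ``(n_insertions + n_deletions) * n_queries``.
    """
    if min(n_insertions, n_deletions, n_queries) < 0:
        raise ValidationError("manifest counts must be >= 0")
    rng = _rng(seed, "validation_manifest")
    svs = [(f"INS{i:04d}", "insertion") for i in range(1, n_insertions + 1)]
    svs += [(f"DEL{i:04d}", "deletion") for i in range(1, n_deletions + 1)]
    queries = [f"Q{i:02d}" for i in range(1, n_queries + 1)]
    rows = [
        {
            "sv_id": sv_id,
            "sv_type": sv_type,
            "query_genome": q,
            "chrom": f"Chr{int(rng.integers(1, 13)):02d}",
            "pos": int(rng.integers(1, 40_000_000)),
        }
        for sv_id, sv_type in svs
        for q in queries
    ]
    return pd.DataFrame(
        rows, columns=["sv_id", "sv_type", "query_genome", "chrom", "pos"]
    )
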