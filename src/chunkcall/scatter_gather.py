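"""Scatter per-chunk jobs to an external caller; gather per-chunk VCFs.

The scatter side renders one shell command per chromosome-split-table (CST)
chunk from a user template containing ``{interval}``, ``{inputs}`` and
``{output}`` placeholders, so any joint-genotyping tool that accepts a
``chrom:start-end`` interval can be plugged in.  A bounded local executor
runs the manifest; cluster submission is out of scope.

The gather side assembles the per-chunk multi-sample VCFs back into one
genome-wide call set with strict guarantees: records must lie inside their
declared chunk, output is ordered by genome-index chromosome order then
position, and a duplicate (chrom, pos, ref, alt) across chunks is an error
unless first-wins deduplication is explicitly requested.

A reference combiner (:func:`reference_joint_genotype`) produces a
multi-sample VCF from per-sample VCFs for one interval: the site set is the
union of in-interval per-sample sites, with missing genotypes where a sample
has no record.  It handles explicit per-site records only — gVCF
reference-block semantics are not modeled — and exists so the gather stage
is testable end-to-end without an external caller.
"""

from __future__ import annotations

import os
import shlex
import subprocess
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from ._vcfio import build_header, copy_header, record_key, samples_of
from .errors import (
    BoundaryError,
    DuplicateRecordError,
    ManifestError,
    UnknownContigError,
    ValidationError,
)
from .gis import ChromosomeSplitTable, ChunkInterval

__all__ = [
    "JobEntry",
    "JobManifest",
    "make_manifest",
    "write_manifest",
    "run_local",
    "reference_joint_genotype",
    "split_vcf_by_cst",
    "gather_chunk_vcfs",
]

_PLACEHOLDERS = ("{interval}", "{inputs}", "{output}")


@dataclass(frozen=True)
class JobEntry:
    chunk: ChunkInterval
    interval_string: str
    command: str
    output_path: str


@dataclass(frozen=True)
class JobManifest:
    """One rendered command per CST chunk, in CST order."""

    entries: Tuple[JobEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def output_paths(self) -> Tuple[str, ...]:
        return tuple(e.output_path for e in self.entries)


def make_manifest(
    cst: ChromosomeSplitTable,
    command_template: str,
    input_paths: Sequence[str | os.PathLike],
    outdir: str | os.PathLike,
) -> JobManifest:
    """Render the per-chunk job list.

    The template must contain all of ``{interval}``, ``{inputs}`` and
    ``{output}``.  Output file names encode chromosome and chunk number
    (``Chr01_0002.vcf``) so they are unique and deterministic.
    """
    for placeholder in _PLACEHOLDERS:
        if placeholder not in command_template:
            raise ManifestError(f"command template lacks required placeholder {placeholder}")
    if not input_paths:
        raise ManifestError("input_paths is empty")
    inputs = " ".join(os.fspath(p) for p in input_paths)
    outdir = Path(outdir)
    entries: List[JobEntry] = []
    for chunk in cst:
        output = str(outdir / f"{chunk.chrom}_{chunk.chunk_no:04d}.vcf")
        command = command_template.format(
            interval=chunk.interval_string, inputs=inputs, output=output
        )
        entries.append(JobEntry(chunk, chunk.interval_string, command, output))
    return JobManifest(tuple(entries))


def write_manifest(
    manifest: JobManifest,
    tsv_path: str | os.PathLike,
    script_path: Optional[str | os.PathLike] = None,
) -> None:
    """Serialize as a TSV (chrom, chunk_no, interval, output, command) and
    optionally as a runnable shell script, one command per line."""
    with open(tsv_path, "w") as fh:
        fh.write("chrom\tchunk_no\tinterval\toutput\tcommand\n")
        for e in manifest:
            fh.write(
                f"{e.chunk.chrom}\t{e.chunk.chunk_no}\t{e.interval_string}\t"
                f"{e.output_path}\t{e.command}\n"
            )
    if script_path is not None:
        with open(script_path, "w") as fh:
            fh.write("#!/bin/sh\nset -e\n")
            for e in manifest:
                fh.write(e.command + "\n")


def run_local(manifest: JobManifest, jobs: int = 1) -> None:
    """Run manifest commands locally, sequentially or with a bounded pool.

    Contract: every per-chunk output is a complete file before gather
    begins; a non-zero exit from any command aborts with its stderr.
    """
    if jobs < 1:
        raise ValidationError(f"jobs must be >= 1, got {jobs}")

    def _run(entry: JobEntry) -> None:
        proc = subprocess.run(
            entry.command, shell=True, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"chunk {entry.chunk.chrom}:{entry.chunk.chunk_no} command failed "
                f"({proc.returncode}): {shlex.split(entry.command)[0]}\n{proc.stderr}"
            )

    if jobs == 1:
        for entry in manifest:
            _run(entry)
    else:
        with ThreadPoolExecutor(max_workers=jobs) as pool:
            for future in [pool.submit(_run, e) for e in manifest]:
                future.result()


def reference_joint_genotype(
    per_sample_vcfs: Sequence[str | os.PathLike],
    interval: ChunkInterval,
    out_path: str | os.PathLike,
) -> int:
    """Combine per-sample VCFs into one multi-sample VCF for one interval.

    Output sites are the union of input sites with ``interval.start <= pos
    <= interval.end``; one genotype column per input file (in input order),
    missing (``./.``) where a sample has no record at a site.  QUAL and the
    filterable INFO annotations are carried from the first contributing
    record per site.  Returns the number of sites written.
    """
    if not per_sample_vcfs:
        raise ValidationError("per_sample_vcfs is empty")

    sample_names: List[str] = []
    contigs: List[Tuple[str, int]] = []
    # keyed (pos, ref) -> {alts (ordered), per-sample allele-string calls, qual, info}
    sites: Dict[Tuple[int, str], dict] = {}

    for i, path in enumerate(per_sample_vcfs):
        with pysam.VariantFile(os.fspath(path)) as vf:
            names = samples_of(vf)
            if len(names) != 1:
                raise ValidationError(f"{path}: expected exactly 1 sample, found {len(names)}")
            sample_names.append(names[0])
            if interval.chrom not in vf.header.contigs:
                raise UnknownContigError(
                    f"{path}: contig {interval.chrom!r} not declared in header"
                )
            if i == 0:
                contigs = [
                    (c.name, c.length or interval.end) for c in vf.header.contigs.values()
                ]
            for rec in vf:
                if rec.chrom != interval.chrom or not interval.contains(rec.pos):
                    continue
                key = (rec.pos, rec.ref or "")
                site = sites.setdefault(
                    key,
                    {"alts": [], "calls": {}, "qual": rec.qual, "info": dict(rec.info)},
                )
                alleles = [rec.ref or ""] + list(rec.alts or ())
                for alt in rec.alts or ():
                    if alt not in site["alts"]:
                        site["alts"].append(alt)
                gt = rec.samples[0].get("GT") or ()
                site["calls"][i] = tuple(
                    None if a is None else alleles[a] for a in gt
                )

    header = build_header(contigs, sample_names)
    n = 0
    with pysam.VariantFile(os.fspath(out_path), "w", header=header) as out:
        for (pos, ref), site in sorted(sites.items()):
            alts = site["alts"]
            alleles = [ref] + alts
            rec = out.new_record(
                contig=interval.chrom,
                start=pos - 1,
                stop=pos - 1 + len(ref),
                alleles=tuple(alleles) if alts else (ref, "."),
            )
            rec.qual = site["qual"]
            for k, v in site["info"].items():
                if k in header.info:
                    rec.info[k] = v
            for i in range(len(sample_names)):
                call = site["calls"].get(i)
                if call is None:
                    rec.samples[i]["GT"] = (None, None)
                else:
                    rec.samples[i]["GT"] = tuple(
                        None if a is None else alleles.index(a) for a in call
                    )
            out.write(rec)
            n += 1
    return n


def split_vcf_by_cst(
    vcf_path: str | os.PathLike,
    cst: ChromosomeSplitTable,
    outdir: str | os.PathLike,
) -> List[str]:
    """Partition a VCF into one file per CST chunk (inverse of gather).

    A record lands in the unique chunk whose inclusive range contains its
    position (a position equal to a chunk's end belongs to that chunk).
    Chunks with no records yield header-only files.  Returns the per-chunk
    paths in CST order.
    """
    import bisect

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    boundaries = cst.boundary_map()
    chunks_by_chrom: Dict[str, List[ChunkInterval]] = {}
    for chunk in cst:
        chunks_by_chrom.setdefault(chunk.chrom, []).append(chunk)

    with pysam.VariantFile(os.fspath(vcf_path)) as vin:
        header = copy_header(vin.header)
        writers: Dict[Tuple[str, int], pysam.VariantFile] = {}
        paths: List[str] = []
        for chunk in cst:
            path = str(outdir / f"{chunk.chrom}_{chunk.chunk_no:04d}.vcf")
            writers[(chunk.chrom, chunk.chunk_no)] = pysam.VariantFile(
                path, "w", header=header
            )
            paths.append(path)
        try:
            for rec in vin:
                ends = boundaries.get(rec.chrom)
                if ends is None:
                    raise UnknownContigError(
                        f"record {rec.chrom}:{rec.pos} on a chromosome absent from the CST"
                    )
                idx = bisect.bisect_left(ends, rec.pos)
                if idx >= len(ends):
                    raise BoundaryError(
                        f"record {rec.chrom}:{rec.pos} beyond the last chunk end {ends[-1]}"
                    )
                chunk = chunks_by_chrom[rec.chrom][idx]
                rec.translate(header)
                writers[(chunk.chrom, chunk.chunk_no)].write(rec)
        finally:
            for w in writers.values():
                w.close()
    return paths


def gather_chunk_vcfs(
    cst: ChromosomeSplitTable,
    chunk_files: Sequence[str | os.PathLike],
    out_path: str | os.PathLike,
    dedupe_boundaries: bool = False,
) -> int:
    """Assemble per-chunk VCFs into one genome-wide call set.

    Requires one file per chunk, in CST order, all sharing identical sample
    columns.  Guarantees: every record lies inside its declared chunk
    (:class:`BoundaryError` otherwise, naming chunk and position); output is
    ordered by CST chromosome order then position; the header is the first
    chunk's plus one provenance line.  A duplicate (chrom, pos, ref, alt)
    across chunks raises :class:`DuplicateRecordError` unless
    ``dedupe_boundaries`` keeps the first occurrence.  Returns the number of
    records written.
    """
    if len(chunk_files) != len(cst):
        raise ValidationError(
            f"expected {len(cst)} chunk files (one per CST entry), got {len(chunk_files)}"
        )

    n_written = 0
    first_samples: Optional[Tuple[str, ...]] = None
    seen_chrom_keys: set = set()
    current_chrom: Optional[str] = None
    last_pos = 0
    out: Optional[pysam.VariantFile] = None
    header: Optional[pysam.VariantHeader] = None
    try:
        for chunk, path in zip(cst, chunk_files):
            with pysam.VariantFile(os.fspath(path)) as vin:
                if first_samples is None:
                    first_samples = samples_of(vin)
                    header = copy_header(vin.header)
                    header.add_line(
                        f"##chunkcall_gather=chunks={len(cst)},chunk_length={cst.chunk_length}"
                    )
                    out = pysam.VariantFile(os.fspath(out_path), "w", header=header)
                elif samples_of(vin) != first_samples:
                    raise ValidationError(
                        f"{path}: sample columns {samples_of(vin)} differ from "
                        f"first chunk's {first_samples}"
                    )
                if chunk.chrom != current_chrom:
                    current_chrom = chunk.chrom
                    seen_chrom_keys.clear()
                    last_pos = 0
                for rec in vin:
                    if rec.chrom != chunk.chrom or not chunk.contains(rec.pos):
                        raise BoundaryError(
                            f"chunk {chunk.chrom}:{chunk.chunk_no} "
                            f"[{chunk.start}-{chunk.end}]: record at "
                            f"{rec.chrom}:{rec.pos} lies outside its chunk"
                        )
                    key = record_key(rec)
                    if key[1:] in seen_chrom_keys:
                        if dedupe_boundaries:
                            continue
                        raise DuplicateRecordError(
                            f"duplicate record {rec.chrom}:{rec.pos} "
                            f"{key[2]}->{','.join(key[3])} across chunks "
                            "(set dedupe_boundaries to keep first occurrence)"
                        )
                    if rec.pos < last_pos:
                        raise ValidationError(
                            f"{path}: records not position-sorted at {rec.chrom}:{rec.pos}"
                        )
                    seen_chrom_keys.add(key[1:])
                    last_pos = rec.pos
                    assert out is not None and header is not None
                    rec.translate(header)
                    out.write(rec)
                    n_written += 1
    finally:
        if out is not None:
            out.close()
    return n_written
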