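import pysam
import pytest
from helpers import record_stream, write_vcf

from chunkcall.errors import (
    BoundaryError,
    DuplicateRecordError,
    ManifestError,
    UnknownContigError,
    ValidationError,
)
from chunkcall.genome_index import GenomeIndex
from chunkcall.gis import ChunkInterval, build_cst
from chunkcall.scatter_gather import (
    gather_chunk_vcfs,
    make_manifest,
    reference_joint_genotype,
    run_local,
    split_vcf_by_cst,
    write_manifest,
)

TEMPLATE = "caller -L {interval} -I {inputs} -O {output}"


class TestMakeManifest:
    def test_one_command_per_chunk_with_its_interval(self, tmp_path):
        cst = build_cst(GenomeIndex((("Chr01", 30),)), 10)
        manifest = make_manifest(cst, TEMPLATE, ["a.g.vcf", "b.g.vcf"], tmp_path)
        assert len(manifest) == 3
        for entry, expected in zip(manifest, ["Chr01:1-10", "Chr01:11-20", "Chr01:21-30"]):
            assert entry.interval_string == expected
            assert expected in entry.command
            assert entry.output_path in entry.command
            assert "a.g.vcf b.g.vcf" in entry.command
        assert len(set(manifest.output_paths)) == 3

    @pytest.mark.parametrize("missing", ["{interval}", "{inputs}", "{output}"])
    def test_template_missing_placeholder_raises(self, tmp_path, missing):
        cst = build_cst(GenomeIndex((("A", 10),)), 5)
        broken = TEMPLATE.replace(missing, "X")
        with pytest.raises(ManifestError, match="placeholder"):
            make_manifest(cst, broken, ["a.vcf"], tmp_path)

    def test_empty_inputs_raise(self, tmp_path):
        cst = build_cst(GenomeIndex((("A", 10),)), 5)
        with pytest.raises(ManifestError, match="empty"):
            make_manifest(cst, TEMPLATE, [], tmp_path)

    def test_serialization_and_local_run(self, tmp_path):
        cst = build_cst(GenomeIndex((("A", 20),)), 10)
        manifest = make_manifest(
            cst, "echo {interval} {inputs} > {output}", ["in.vcf"], tmp_path
        )
        tsv, script = tmp_path / "jobs.tsv", tmp_path / "jobs.sh"
        write_manifest(manifest, tsv, script)
        assert tsv.read_text().count("\n") == 3  # header + 2 jobs
        assert script.read_text().startswith("#!/bin/sh")
        run_local(manifest, jobs=2)
        for entry in manifest:
            assert entry.interval_string in open(entry.output_path).read()

    def test_failing_command_aborts(self, tmp_path):
        cst = build_cst(GenomeIndex((("A", 10),)), 10)
        manifest = make_manifest(cst, "false {interval} {inputs} {output}", ["x"], tmp_path)
        with pytest.raises(RuntimeError, match="command failed"):
            run_local(manifest)


class TestReferenceJointGenotype:
    CONTIGS = (("Chr01", 100),)

    def _sample(self, tmp_path, name, positions):
        return write_vcf(
            tmp_path / f"{name}.vcf",
            self.CONTIGS,
            [name],
            [
                {"chrom": "Chr01", "pos": p, "ref": "A", "alts": ("G",),
                 "gts": {name: (0, 1)}}
                for p in positions
            ],
        )

    def test_disjoint_sites_get_missing_genotypes(self, tmp_path):
        vcfs = [self._sample(tmp_path, "s1", [5]), self._sample(tmp_path, "s2", [9])]
        out = tmp_path / "joint.vcf"
        n = reference_joint_genotype(vcfs, ChunkInterval("Chr01", 1, 1, 10), out)
        assert n == 2
        stream = record_stream(out)
        assert [(r[1], r[4]) for r in stream] == [
            (5, ((0, 1), (None, None))),
            (9, ((None, None), (0, 1))),
        ]

    def test_shared_site_keeps_both_calls(self, tmp_path):
        vcfs = [self._sample(tmp_path, "s1", [5]), self._sample(tmp_path, "s2", [5])]
        out = tmp_path / "joint.vcf"
        assert reference_joint_genotype(vcfs, ChunkInterval("Chr01", 1, 1, 10), out) == 1
        assert record_stream(out)[0][4] == ((0, 1), (0, 1))

    def test_record_past_interval_end_excluded(self, tmp_path):
        vcfs = [self._sample(tmp_path, "s1", [10, 11])]
        out = tmp_path / "joint.vcf"
        assert reference_joint_genotype(vcfs, ChunkInterval("Chr01", 1, 1, 10), out) == 1
        assert [r[1] for r in record_stream(out)] == [10]

    def test_unknown_contig_raises(self, tmp_path):
        vcfs = [self._sample(tmp_path, "s1", [5])]
        with pytest.raises(UnknownContigError):
            reference_joint_genotype(vcfs, ChunkInterval("Chr99", 1, 1, 10), tmp_path / "o.vcf")

    def test_site_count_equals_union_of_per_sample_sets(self, tmp_path, cohort):
        chrom, length = cohort.frame.records[0]
        interval = ChunkInterval(chrom, 1, 1, length)
        out = tmp_path / "joint.vcf"
        n = reference_joint_genotype(list(cohort.sample_paths), interval, out)
        union = set()
        for path in cohort.sample_paths:
            with pysam.VariantFile(path) as vf:
                union |= {rec.pos for rec in vf if rec.chrom == chrom}
        assert n == len(union)


class TestSplitAndGather:
    def _toy(self, tmp_path, positions, chrom_len=10):
        return write_vcf(
            tmp_path / "toy.vcf",
            (("A", chrom_len),),
            ["s1"],
            [
                {"chrom": "A", "pos": p, "ref": "C", "alts": ("T",), "gts": {"s1": (0, 1)}}
                for p in positions
            ],
        )

    def test_split_places_records_in_containing_chunks(self, tmp_path):
        cst = build_cst(GenomeIndex((("A", 10),)), 5)
        paths = split_vcf_by_cst(self._toy(tmp_path, [3, 7]), cst, tmp_path / "chunks")
        assert [r[1] for r in record_stream(paths[0])] == [3]
        assert [r[1] for r in record_stream(paths[1])] == [7]

    def test_position_equal_to_chunk_end_goes_to_that_chunk(self, tmp_path):
        cst = build_cst(GenomeIndex((("A", 10),)), 5)
        paths = split_vcf_by_cst(self._toy(tmp_path, [5]), cst, tmp_path / "chunks")
        assert [r[1] for r in record_stream(paths[0])] == [5]
        assert record_stream(paths[1]) == []

    def test_empty_chunk_yields_header_only_file(self, tmp_path):
        cst = build_cst(GenomeIndex((("A", 10),)), 5)
        paths = split_vcf_by_cst(self._toy(tmp_path, [2]), cst, tmp_path / "chunks")
        assert record_stream(paths[1]) == []
        with pysam.VariantFile(paths[1]) as vf:
            assert tuple(vf.header.samples) == ("s1",)

    def test_unknown_chromosome_raises(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "t.vcf", (("A", 10), ("B", 10)), ["s1"],
            [{"chrom": "B", "pos": 1, "ref": "C", "alts": ("T",), "gts": {"s1": (0, 1)}}],
        )
        cst = build_cst(GenomeIndex((("A", 10),)), 5)
        with pytest.raises(UnknownContigError):
            split_vcf_by_cst(vcf, cst, tmp_path / "chunks")

    def test_gather_concatenates_in_coordinate_order(self, tmp_path, cohort):
        cst = build_cst(cohort.frame, 17_000)
        paths = split_vcf_by_cst(cohort.joint_path, cst, tmp_path / "chunks")
        out = tmp_path / "gathered.vcf"
        n = gather_chunk_vcfs(cst, paths, out)
        assert n == len(cohort.truth)
        assert record_stream(out) == record_stream(cohort.joint_path)

    def test_record_outside_chunk_is_a_boundary_error(self, tmp_path):
        cst = build_cst(GenomeIndex((("A", 10),)), 5)
        # chunk 1 file holds a record at pos 6, one past the chunk end
        bad = write_vcf(
            tmp_path / "c1.vcf", (("A", 10),), ["s1"],
            [{"chrom": "A", "pos": 6, "ref": "C", "alts": ("T",), "gts": {"s1": (0, 1)}}],
        )
        empty = write_vcf(tmp_path / "c2.vcf", (("A", 10),), ["s1"], [])
        with pytest.raises(BoundaryError, match=r"A:1.*6|6.*outside"):
            gather_chunk_vcfs(cst, [bad, empty], tmp_path / "out.vcf")

    def test_duplicate_across_chunks_error_and_dedupe(self, tmp_path):
        # duplicates can only collide within the same chromosome stream, so
        # plant the same record in both halves via a deliberately broken pair
        cst = build_cst(GenomeIndex((("A", 10),)), 5)
        rec5 = {"chrom": "A", "pos": 5, "ref": "C", "alts": ("T",), "gts": {"s1": (0, 1)}}
        c1 = write_vcf(tmp_path / "c1.vcf", (("A", 10),), ["s1"], [rec5])
        # a record at pos 5 inside chunk 2's file is both a boundary and a
        # duplicate problem; use pos 5 duplicated inside chunk 1 instead
        c1dup = write_vcf(tmp_path / "c1dup.vcf", (("A", 10),), ["s1"], [rec5, rec5])
        c2 = write_vcf(tmp_path / "c2.vcf", (("A", 10),), ["s1"], [])
        with pytest.raises(DuplicateRecordError):
            gather_chunk_vcfs(cst, [c1dup, c2], tmp_path / "out.vcf")
        n = gather_chunk_vcfs(cst, [c1dup, c2], tmp_path / "out2.vcf", dedupe_boundaries=True)
        assert n == 1
        del c1

    def test_sample_mismatch_rejected(self, tmp_path):
        cst = build_cst(GenomeIndex((("A", 10),)), 5)
        c1 = write_vcf(tmp_path / "c1.vcf", (("A", 10),), ["s1"], [])
        c2 = write_vcf(tmp_path / "c2.vcf", (("A", 10),), ["other"], [])
        with pytest.raises(ValidationError, match="sample columns"):
            gather_chunk_vcfs(cst, [c1, c2], tmp_path / "out.vcf")

    def test_wrong_file_count_rejected(self, tmp_path):
        cst = build_cst(GenomeIndex((("A", 10),)), 5)
        c1 = write_vcf(tmp_path / "c1.vcf", (("A", 10),), ["s1"], [])
        with pytest.raises(ValidationError, match="chunk files"):
            gather_chunk_vcfs(cst, [c1], tmp_path / "out.vcf")

    @pytest.mark.parametrize("chunk_length", [997, 5_000, 33_333, 10**7])
    def test_split_gather_identity_for_arbitrary_chunk_lengths(
        self, tmp_path, cohort, chunk_length
    ):
        cst = build_cst(cohort.frame, chunk_length)
        outdir = tmp_path / f"chunks_{chunk_length}"
        paths = split_vcf_by_cst(cohort.joint_path, cst, outdir)
        out = tmp_path / f"gathered_{chunk_length}.vcf"
        gather_chunk_vcfs(cst, paths, out)
        assert record_stream(out) == record_stream(cohort.joint_path)
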