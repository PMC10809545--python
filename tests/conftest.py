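import pytest

from chunkcall.fixtures import synth_cohort, synth_genome_index


@pytest.fixture(scope="session")
def small_frame():
    """Three short chromosomes; deterministic."""
    return synth_genome_index(7, n_chrom=3, min_len=50_000, max_len=100_000)


@pytest.fixture(scope="session")
def cohort(small_frame, tmp_path_factory):
    """A 5-sample cohort (~100 sites) with planted truth."""
    return synth_cohort(
        7, small_frame, n_samples=5,
        outdir=tmp_path_factory.mktemp("cohort"), snp_rate=5e-4,
    )
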