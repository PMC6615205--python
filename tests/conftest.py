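import pytest
from hypothesis import HealthCheck, settings

import smurfseq as sq

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome() -> sq.ReferenceGenome:
    """Two 500 kb chromosomes at GC 0.5 — shared, treat as read-only."""
    return sq.generate_genome(2, 500_000, 0.5, seed=101)


@pytest.fixture(scope="session")
def small_digest(small_genome):
    return sq.digest(small_genome, sq.SAQAI)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return sq.build_index(small_genome, 12)


@pytest.fixture(scope="session")
def neutral_truth(small_genome):
    return sq.plant_cnv(small_genome, [])


@pytest.fixture(scope="session")
def clean_reads(small_genome, small_digest, neutral_truth):
    """Error-free concatenated reads with >=100 bp fragments."""
    frags = sq.sample_fragments(
        small_digest, neutral_truth, 800, seed=5, min_length=100
    )
    return sq.concatenate(frags, small_genome, 6800)


@pytest.fixture(scope="session")
def noisy_reads(clean_reads):
    model = sq.ErrorModel(seed=17)
    return [sq.apply_errors(r, model) for r in clean_reads]
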