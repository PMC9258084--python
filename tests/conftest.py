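import numpy as np
import pytest

from bsaseq import BulkCounts, ReadCounts, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A miniature experiment used by fast pipeline tests."""
    return SimulationConfig(
        n_individuals=60, n_loci=400, chrom_length_bp=4_000_000,
        lambda_morgans=1.0, k=1.0, qtl_locus=200, bulk_fraction=0.10,
        depth=40, window_bp=300_000.0, ed_window_snps=20, seed=7,
    )


def make_counts(alt_high, ref_high, alt_low, ref_low, positions=None):
    """BulkCounts from plain count arrays (positions default to 1..n)."""
    alt_high = np.atleast_1d(alt_high)
    if positions is None:
        positions = np.arange(1.0, alt_high.size + 1.0)
    positions = np.asarray(positions, dtype=float)
    return BulkCounts(
        positions=positions,
        high=ReadCounts(positions, np.atleast_1d(alt_high),
                        np.atleast_1d(ref_high)),
        low=ReadCounts(positions, np.atleast_1d(alt_low),
                       np.atleast_1d(ref_low)),
    )


@pytest.fixture
def counts_factory():
    return make_counts
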