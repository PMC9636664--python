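import numpy as np
import pytest

from tadconcord import GenomicBinning, SyntheticSpec, TadSet, generate_partition


@pytest.fixture
def binning():
    return GenomicBinning("chr10", 40_000, 100)


@pytest.fixture
def make_tadset(binning):
    """Factory: TadSet from (start, end) bin pairs on the shared binning."""

    def _make(intervals, label="test", bins=None):
        b = binning if bins is None else GenomicBinning("chr10", 40_000, bins)
        return TadSet.from_intervals(label, b, intervals)

    return _make


@pytest.fixture
def random_tadset():
    """Factory: random partition (optionally gapped) for a given seed."""

    def _make(seed, n_bins=200, gapped=True, label=None):
        spec = SyntheticSpec(
            n_bins=n_bins,
            min_size=3,
            max_size=20,
            gap_prob=0.3 if gapped else 0.0,
            gap_max=4,
            seed=seed,
        )
        return generate_partition(spec, label=label or f"rand{seed}")

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
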