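import numpy as np
import pytest

from polyprofile import FixtureSpec, PeakVolumes, make_count_table, make_trace


@pytest.fixture(scope="session")
def yeast_spec() -> FixtureSpec:
    """A small but fully realistic yeast-like synthetic experiment."""
    return FixtureSpec(seed=7, n_genes=600, depth_fp=1_000_000, depth_rna=1_000_000)


@pytest.fixture(scope="session")
def yeast_counts(yeast_spec):
    """(counts, truth, params) for the shared yeast-like fixture."""
    return make_count_table(yeast_spec)


@pytest.fixture(scope="session")
def ten_peak_volumes() -> PeakVolumes:
    """Smooth 10-peak profile; every peak carries non-negligible mass."""
    v = np.array([0.12, 0.20, 0.18, 0.13, 0.10, 0.08, 0.06, 0.05, 0.04, 0.04])
    return PeakVolumes(dict(zip(np.arange(1.0, 11.0), v / v.sum())))


@pytest.fixture(scope="session")
def noise_free_trace(ten_peak_volumes):
    """Noise-free 10-peak trace with its exact generating model."""
    spec = FixtureSpec(seed=3, trace_noise_sd=0.0)
    return make_trace(spec, ten_peak_volumes)
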