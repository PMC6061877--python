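"""Shared fixtures: small deterministic histograms, components and cohorts."""

import numpy as np
import pytest

from lpmadc import BinningScheme, PairedHistogram
from lpmadc.lpm_core import CONTROL, TREATMENT, ComponentSet, LPModel


@pytest.fixture(scope="session")
def small_binning():
    """Eight uniform ADC bins over [0, 3e-3] mm^2/s."""
    return BinningScheme.uniform(8)


@pytest.fixture
def disjoint_components(small_binning):
    """Two components with disjoint support: low vs high ADC bins."""
    B = small_binning.n_bins
    p1 = np.zeros((B, 2))
    p1[:B // 2, :] = 1.0
    p2 = np.zeros((B, 2))
    p2[B // 2:, :] = 1.0
    p1 /= p1.sum()
    p2 /= p2.sum()
    return ComponentSet(np.stack([p1, p2]), (CONTROL, CONTROL))


def make_histogram(counts, binning, tumor_id="t"):
    return PairedHistogram(np.asarray(counts), tumor_id, binning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_components(rng, n_control, n_treatment, n_bins=8):
    """Strictly positive random PMFs (no exact zeros, safe for fits)."""
    K = n_control + n_treatment
    pmfs = rng.dirichlet(np.ones(n_bins * 2) * 2.0, size=K)
    pmfs = pmfs.reshape(K, n_bins, 2)
    labels = (CONTROL,) * n_control + (TREATMENT,) * n_treatment
    return ComponentSet(pmfs, labels)


def model_from_components(components, n_bins=8):
    binning = BinningScheme.uniform(n_bins)
    return LPModel(components, binning, {}, {})
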