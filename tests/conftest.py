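import numpy as np
import pytest

from grbs import SimConfig, simulate_all


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact full dataset (no tracks) shared across read-only tests."""
    cfg = SimConfig(
        seed=11, n_chroms=2, chrom_length_bp=400_000, peak_region_fraction=0.6,
        n_gr_peaks=150, n_background_brg1=30, n_genes=400,
    )
    return simulate_all(cfg, with_tracks=False)


@pytest.fixture(scope="session")
def sparse_dataset():
    """Default-like geometry (peak territory on multi-Mb chromosomes) so
    50-kb-radius statistics behave as under the full-size conditions."""
    cfg = SimConfig(
        seed=13, n_chroms=2, chrom_length_bp=2_000_000, peak_region_fraction=0.3,
        n_gr_peaks=200, n_background_brg1=40, n_genes=500,
    )
    return simulate_all(cfg, with_tracks=False)


@pytest.fixture(scope="session")
def signal_dataset():
    """Class-III-heavy dataset with BRG1 tracks for signal tests."""
    cfg = SimConfig(
        seed=7, n_chroms=2, chrom_length_bp=500_000, peak_region_fraction=0.8,
        n_gr_peaks=300, n_background_brg1=30,
        class_mix={"I": 0.1, "II": 0.1, "III": 0.8, "other": 0.0},
        n_genes=100, track_factors=("BRG1",),
    )
    return simulate_all(cfg)
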