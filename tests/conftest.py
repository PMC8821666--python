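import numpy as np
import pytest

from dialib import (PreprocessConfig, SimConfig, generate_benchmark,
                    read_query_spectra, read_sptxt, zero_noise_config)
from dialib.preprocess import BinnedSpectrum, normalize


def random_binned(rng: np.random.Generator, max_bins: int = 20,
                  lo: int = 100, hi: int = 1500) -> BinnedSpectrum:
    """A random sparse normalized spectrum with 1..max_bins occupied bins."""
    n = int(rng.integers(1, max_bins + 1))
    bins = rng.choice(np.arange(lo, hi), size=n, replace=False)
    intensities = rng.uniform(0.05, 1.0, size=n)
    return normalize(BinnedSpectrum(
        bins={int(b): float(v) for b, v in zip(bins, intensities)}))


def overlapping_pair(rng: np.random.Generator, max_bins: int = 20):
    """A random normalized pair guaranteed to share at least one bin."""
    q = random_binned(rng, max_bins)
    l = random_binned(rng, max_bins)
    shared = int(rng.choice(list(q.bins)))
    raw = {**{k: float(v) for k, v in l.bins.items()},
           shared: float(rng.uniform(0.05, 1.0))}
    return q, normalize(BinnedSpectrum(raw))


@pytest.fixture(scope="session")
def zero_noise_benchmark(tmp_path_factory):
    """200-peptide noise-free benchmark: queries == their library entries."""
    out = tmp_path_factory.mktemp("zero_noise")
    cfg = zero_noise_config(n_peptides=200, seed=11)
    sptxt, mgfs, truth = generate_benchmark(cfg, out)
    lib = read_sptxt(sptxt)
    queries = [q for p in sorted(mgfs.values()) for q in read_query_spectra(p)]
    return lib, queries, truth


@pytest.fixture(scope="session")
def mixed_benchmark(tmp_path_factory):
    """Noisy benchmark with 40% junk queries — exercises the validator."""
    out = tmp_path_factory.mktemp("mixed")
    cfg = SimConfig(n_peptides=150, seed=23, dropout_prob=0.3,
                    noise_peaks=12.0, intensity_cv=0.5, chimera_prob=0.15)
    sptxt, mgfs, truth = generate_benchmark(cfg, out, n_queries=400,
                                            null_fraction=0.4)
    lib = read_sptxt(sptxt)
    queries = [q for p in sorted(mgfs.values()) for q in read_query_spectra(p)]
    return lib, queries, truth


@pytest.fixture()
def default_cfg():
    return PreprocessConfig()
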