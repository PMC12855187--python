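import numpy as np
import pytest

import psametab as pm


@pytest.fixture(scope="session")
def default_cohort():
    """One reference synthetic cohort at default parameters (n=29/33)."""
    return pm.generate_cohort(seed=20)


@pytest.fixture(scope="session")
def rel_conc(default_cohort):
    return pm.relative_concentrations(default_cohort.concentrations)


@pytest.fixture(scope="session")
def small_spectra():
    """A small rendered spectrum set for bucketing tests."""
    sc = pm.generate_cohort(n_psa=5, n_hc=5, seed=7, spectra=True)
    return sc.spectra


def strong_signal(n1=20, n2=20, p=6, delta=3.0, seed=0):
    """Two well-separated Gaussian classes for model-quality tests."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n1 + n2, p))
    X[:n1, :2] += delta
    y = np.array(["A"] * n1 + ["B"] * n2)
    return X, y
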