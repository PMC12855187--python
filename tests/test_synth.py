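"""Synthetic-cohort generator: determinism, calibration, copula."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import psametab as pm
from psametab.synth import GroupParams, DapsaLink, solve_truncated_normal


def test_seed_determinism():
    a = pm.generate_cohort(seed=11, spectra=True, n_psa=4, n_hc=4)
    b = pm.generate_cohort(seed=11, spectra=True, n_psa=4, n_hc=4)
    pd.testing.assert_frame_equal(a.concentrations, b.concentrations)
    pd.testing.assert_frame_equal(a.cohort, b.cohort)
    np.testing.assert_array_equal(a.spectra.intensities, b.spectra.intensities)


def test_glucose_mean_recovery_large_n():
    conc, cohort = pm.generate_concentrations(n_psa=10000, n_hc=2, seed=3)
    psa_glucose = conc.loc[cohort.group == "PsA", "glucose"]
    assert abs(psa_glucose.mean() - 52.43) < 0.2
    assert abs(psa_glucose.std() - 5.242) < 0.2


def test_uncorrelated_params_give_zero_correlation():
    params = GroupParams.default(rho=0.0)
    conc, cohort = pm.generate_concentrations(params, n_psa=5000, n_hc=2, seed=4)
    R = np.corrcoef(conc[cohort.group == "PsA"].to_numpy(), rowvar=False)
    off = R[~np.eye(R.shape[0], dtype=bool)]
    assert np.max(np.abs(off)) < 0.06


def test_concentrations_nonnegative_and_counts(default_cohort):
    assert (default_cohort.concentrations.to_numpy() >= 0).all()
    assert (default_cohort.cohort.group == "PsA").sum() == 29
    assert (default_cohort.cohort.group == "HC").sum() == 33


def test_non_positive_definite_correlation_rejected():
    R = np.full((13, 13), 0.99)
    np.fill_diagonal(R, 1.0)
    R[0, 1] = R[1, 0] = -0.99
    base = GroupParams.default()
    with pytest.raises(ValueError, match="positive definite"):
        GroupParams(metabolite_names=base.metabolite_names,
                    means_psa=base.means_psa, sds_psa=base.sds_psa,
                    means_hc=base.means_hc, sds_hc=base.sds_hc,
                    correlation=R)


def test_truncated_normal_calibration_against_quadrature():
    mu, sigma = solve_truncated_normal(25.2, 10.4, 14.0)
    a = (14.0 - mu) / sigma
    mean, var = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma,
                                      moments="mv")
    assert abs(mean - 25.2) < 1e-8
    assert abs(np.sqrt(var) - 10.4) < 1e-8


def test_dapsa_marginal_large_n():
    conc, cohort = pm.generate_concentrations(n_psa=10000, n_hc=2, seed=5)
    cohort = pm.generate_dapsa(cohort, conc, seed=6)
    d = cohort.loc[cohort.group == "PsA", "dapsa"]
    assert d.notna().all()
    assert (d > 14).all()
    assert cohort.loc[cohort.group == "HC", "dapsa"].isna().all()
    assert abs(d.mean() - 25.2) < 0.3
    assert abs(d.std() - 10.4) < 0.3


def test_dapsa_independent_when_targets_zero():
    link = DapsaLink(target_spearman={})
    conc, cohort = pm.generate_concentrations(n_psa=5000, n_hc=2, seed=7)
    cohort = pm.generate_dapsa(cohort, conc, link, seed=8)
    psa = cohort.group == "PsA"
    r = stats.spearmanr(conc.loc[psa, "leucine"],
                        cohort.loc[psa, "dapsa"]).statistic
    assert abs(r) < 0.05


def test_copula_spearman_convergence_large_n():
    """Achieved rank correlations converge to the targets (n=1e5)."""
    conc, cohort = pm.generate_concentrations(n_psa=100_000, n_hc=2, seed=9)
    cohort = pm.generate_dapsa(cohort, conc, seed=10)
    psa = cohort.group == "PsA"
    d = cohort.loc[psa, "dapsa"]
    for metab, target in [("alanine", 0.384), ("leucine", 0.487)]:
        r = stats.spearmanr(conc.loc[psa, metab], d).statistic
        assert abs(r - target) < 0.01, metab


def test_infeasible_joint_correlation_raises():
    link = DapsaLink(target_spearman={"alanine": 0.95, "leucine": -0.95})
    conc, cohort = pm.generate_concentrations(n_psa=50, n_hc=2, seed=11)
    with pytest.raises(ValueError, match="alanine"):
        pm.generate_dapsa(cohort, conc, link, seed=12)


# --- spectrum renderer ---------------------------------------------------

def _library_zero_noise():
    lib = pm.SpectralLibrary.default()
    lib.noise_sd = 0.0
    lib.jitter_sd = 0.0
    return lib


def test_zero_concentrations_give_flat_spectrum_except_tsp_and_water():
    conc = pd.DataFrame(0.0, index=["s1"], columns=pm.METABOLITES)
    spec = pm.render_spectra(conc, _library_zero_noise(), seed=0)
    ppm, y = spec.ppm, spec.intensities[0]
    mask = (ppm > 0.2) & ((ppm < 4.5) | (ppm > 5.4))
    assert np.max(y[mask]) < 1e-3 * np.max(y)
    assert y[np.argmin(np.abs(ppm - 0.0))] > 0       # TSP
    assert y[np.argmin(np.abs(ppm - 4.95))] > 0      # water band


def test_doubling_concentration_doubles_multiplet_area():
    lib = _library_zero_noise()
    cols = ["alanine"]
    c1 = pd.DataFrame([[2.0]], index=["a"], columns=cols)
    c2 = pd.DataFrame([[4.0]], index=["a"], columns=cols)
    s1 = pm.render_spectra(c1, lib, seed=0)
    s2 = pm.render_spectra(c2, lib, seed=0)
    sel = (s1.ppm > 1.37) & (s1.ppm < 1.57)  # isolated methyl doublet region
    a1 = np.trapezoid(s1.intensities[0][sel], s1.ppm[sel])
    a2 = np.trapezoid(s2.intensities[0][sel], s2.ppm[sel])
    # tiny deviation from exact doubling comes from the constant TSP tail
    assert a2 == pytest.approx(2 * a1, rel=1e-3)


def test_jitter_sd_recovered_from_apex_positions():
    """With jitter_sd=0.005 the apex of an isolated multiplet varies
    across samples with an SD near 0.005 ppm (apexes located numerically
    across 100 samples)."""
    lib = pm.SpectralLibrary.default()
    lib.noise_sd = 0.0
    lib.jitter_sd = 0.005
    conc = pd.DataFrame(5.0, index=[f"s{i}" for i in range(100)],
                        columns=["alanine"])
    spec = pm.render_spectra(conc, lib, n_points=2 ** 15, seed=13)
    sel = (spec.ppm > 1.42) & (spec.ppm < 1.52)
    apexes = spec.ppm[sel][np.argmax(spec.intensities[:, sel], axis=1)]
    assert 0.003 < np.std(apexes, ddof=1) < 0.007


def test_missing_library_entry_listed():
    conc = pd.DataFrame([[1.0, 1.0]], index=["s"],
                        columns=["alanine", "notametabolite"])
    with pytest.raises(ValueError, match="notametabolite"):
        pm.render_spectra(conc, seed=0)
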