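"""Logistic biomarker panel, ROC/AUC, DeLong CI, CV and permutation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import psametab as pm

NINE = ["leucine", "serine", "alanine", "glucose", "methionine",
        "isoleucine", "valine", "glycylproline", "glutamine"]

# group mean relative concentrations of the nine panel metabolites
HC_MEANS = {"leucine": 3.124, "serine": 6.008, "alanine": 8.402,
            "glucose": 48.340, "methionine": 0.8190, "isoleucine": 1.688,
            "valine": 4.769, "glycylproline": 3.411, "glutamine": 11.080}
PSA_MEANS = {"leucine": 2.601, "serine": 5.2170, "alanine": 7.010,
             "glucose": 52.43, "methionine": 0.6879, "isoleucine": 1.500,
             "valine": 4.189, "glycylproline": 4.353, "glutamine": 9.739}


def test_fixed_panel_at_group_mean_vectors():
    """Independent arithmetic oracle: the published coefficients evaluated
    at the two group-mean vectors land on opposite sides of the published
    0.38 cutoff (healthy-control side above, patient side below)."""
    panel = pm.load_fixed_panel()
    for means, side in [(HC_MEANS, "above"), (PSA_MEANS, "below")]:
        logit = panel.intercept + sum(panel.coefficients[m] * means[m]
                                      for m in panel.coefficients)
        p_oracle = 1.0 / (1.0 + np.exp(-logit))
        scored = pm.score_fixed_panel(
            pd.DataFrame([means], index=["mean_vector"]))
        assert scored.P.iloc[0] == pytest.approx(p_oracle, abs=1e-12)
        if side == "above":
            assert scored.P.iloc[0] > panel.threshold
            assert scored.call.iloc[0] == "HC"
        else:
            assert scored.P.iloc[0] < panel.threshold
            assert scored.call.iloc[0] == "other"


def test_fixed_panel_zero_coefficients_give_half():
    panel = pm.FixedPanel(name="null", intercept=0.0,
                          coefficients={m: 0.0 for m in NINE},
                          threshold=0.5, positive_class="HC")
    conc = pd.DataFrame(np.random.default_rng(0).uniform(1, 50, (4, 9)),
                        columns=NINE)
    out = pm.score_fixed_panel(conc, panel)
    np.testing.assert_allclose(out.P, 0.5)


def test_fixed_panel_monotone_in_leucine():
    base = dict(PSA_MEANS)
    rows = []
    for leu in np.linspace(1.0, 5.0, 7):
        rows.append({**base, "leucine": leu})
    out = pm.score_fixed_panel(pd.DataFrame(rows))
    assert np.all(np.diff(out.P) > 0)


def test_fixed_panel_missing_column_lists_requirements():
    conc = pd.DataFrame([[1.0]], columns=["leucine"])
    with pytest.raises(ValueError, match="glutamine"):
        pm.score_fixed_panel(conc)


def test_roc_perfect_and_random():
    labels = np.array(["P"] * 20 + ["N"] * 20)
    perfect = np.concatenate([np.ones(20), np.zeros(20)])
    assert pm.roc_curve(perfect, labels, "P").auc == pytest.approx(1.0)
    rng = np.random.default_rng(4)
    labels_big = np.array(["P", "N"] * 500)
    rand = rng.normal(size=1000)
    assert abs(pm.roc_curve(rand, labels_big, "P").auc - 0.5) < 0.06
    curve = pm.roc_curve(rand, labels_big, "P")
    assert curve.fpr[0] == 0 and curve.tpr[0] == 0
    assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
    assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)


@pytest.mark.parametrize("seed,with_ties", [(0, False), (1, True), (2, True)])
def test_auc_equals_mann_whitney_identity(seed, with_ties):
    rng = np.random.default_rng(seed)
    n1, n2 = 17, 23
    pos = rng.normal(1.0, 1.0, n1)
    neg = rng.normal(0.0, 1.0, n2)
    if with_ties:
        pos = np.round(pos)
        neg = np.round(neg)
    scores = np.concatenate([pos, neg])
    labels = np.array(["P"] * n1 + ["N"] * n2)
    auc = pm.roc_curve(scores, labels, "P").auc
    U = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    assert auc == pytest.approx(U / (n1 * n2), abs=1e-12)


def test_label_swap_maps_auc_and_negates_coefficients(rel_conc,
                                                      default_cohort):
    y = default_cohort.cohort.group
    m_hc = pm.fit_logistic(rel_conc[NINE], y, positive_class="HC")
    m_psa = pm.fit_logistic(rel_conc[NINE], y, positive_class="PsA")
    probs = m_hc.predict_proba(rel_conc)
    auc_hc = pm.roc_curve(probs, y.to_numpy(), "HC").auc
    auc_swapped = pm.roc_curve(probs, y.to_numpy(), "PsA").auc
    assert auc_swapped == pytest.approx(1.0 - auc_hc, abs=1e-12)
    np.testing.assert_allclose(m_psa.coefficients, -m_hc.coefficients,
                               rtol=1e-4, atol=1e-6)


def test_logistic_score_equation_and_symmetry():
    # symmetric single-predictor data: intercept ~ 0
    x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
    conc = pd.DataFrame({"m": x})
    labels = np.array(["N", "N", "N", "P", "P", "P"])
    model = pm.fit_logistic(conc, labels, positive_class="P")
    assert abs(model.intercept) < 1e-3
    # MLE score equation: fitted probabilities sum to the positive count
    rng = np.random.default_rng(5)
    conc2 = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
    labels2 = np.array(["P"] * 18 + ["N"] * 22)
    conc2.iloc[:18] += 0.8
    m2 = pm.fit_logistic(conc2, labels2, positive_class="P")
    assert m2.predict_proba(conc2).sum() == pytest.approx(18.0, abs=1e-4)


def test_irls_matches_statsmodels_mle():
    """On well-conditioned data the ridge-stabilized IRLS fit agrees with
    an independent maximum-likelihood implementation."""
    import statsmodels.api as sm
    rng = np.random.default_rng(21)
    X = rng.normal(size=(120, 3))
    logit = 0.4 + X @ np.array([0.8, -0.5, 0.2])
    ybin = (rng.uniform(size=120) < 1 / (1 + np.exp(-logit))).astype(float)
    if ybin.min() == ybin.max():  # pragma: no cover
        pytest.skip("degenerate draw")
    conc = pd.DataFrame(X, columns=list("abc"))
    labels = np.where(ybin == 1, "P", "N")
    model = pm.fit_logistic(conc, labels, positive_class="P",
                            ci_method="none")
    ref = sm.Logit(ybin, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(model.intercept, ref.params[0], atol=1e-5)
    np.testing.assert_allclose(model.coefficients.to_numpy(),
                               ref.params[1:], atol=1e-5)


def test_constant_predictor_named():
    conc = pd.DataFrame({"good": [1.0, 2.0, 3.0, 4.0],
                         "flat": [5.0, 5.0, 5.0, 5.0]})
    with pytest.raises(ValueError, match="flat"):
        pm.fit_logistic(conc, np.array(["A", "A", "B", "B"]),
                        positive_class="A")


def test_separation_flagged():
    conc = pd.DataFrame({"m": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]})
    labels = np.array(["N"] * 3 + ["P"] * 3)
    with pytest.warns(UserWarning, match="separation"):
        model = pm.fit_logistic(conc, labels, positive_class="P")
    assert model.separation
    assert np.isfinite(model.coefficients).all()


def test_delong_ci_contains_auc_and_shrinks_with_n():
    rng = np.random.default_rng(6)

    def width(n, seed):
        r = np.random.default_rng(seed)
        scores = np.concatenate([r.normal(1, 1, n), r.normal(0, 1, n)])
        labels = np.array(["P"] * n + ["N"] * n)
        lo, hi = pm.auc_ci(scores, labels, "P")
        auc = pm.roc_curve(scores, labels, "P").auc
        assert lo <= auc <= hi
        return hi - lo

    w_small = np.median([width(10, s) for s in range(9)])
    w_large = np.median([width(100, s + 100) for s in range(9)])
    assert w_large < w_small


def test_degenerate_auc_falls_back_to_bootstrap():
    scores = np.concatenate([np.ones(6), np.zeros(6)])
    labels = np.array(["P"] * 6 + ["N"] * 6)
    with pytest.warns(UserWarning, match="bootstrap"):
        lo, hi = pm.auc_ci(scores, labels, "P")
    assert lo <= 1.0 <= hi + 1e-12


def test_cv_and_permute_strong_signal(rel_conc, default_cohort):
    cv, p, obs = pm.cv_and_permute(rel_conc[NINE],
                                   default_cohort.cohort.group,
                                   n_cv=20, n_perm=99, seed=3)
    assert p == pytest.approx(1.0 / 100)       # empirical floor
    assert obs > 0.8
    # overfitting direction: held-out AUC no better than resubstitution
    assert cv.mean() <= obs + 0.02


def test_cv_and_permute_null_signal():
    rng = np.random.default_rng(7)
    ps = []
    for s in range(5):
        conc = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        labels = np.array(["P", "N"] * 15)
        _, p, _ = pm.cv_and_permute(conc, labels, positive_class="P",
                                    n_cv=10, n_perm=60, seed=s)
        ps.append(p)
    assert np.median(ps) > 0.05


def test_cv_auc_below_resubstitution_on_average():
    """Monte-Carlo CV AUC <= resubstitution AUC in expectation."""
    rng = np.random.default_rng(8)
    diffs = []
    for s in range(30):
        conc = pd.DataFrame(rng.normal(size=(24, 4)), columns=list("abcd"))
        conc.iloc[:12] += 0.5
        labels = np.array(["P"] * 12 + ["N"] * 12)
        cv, _, obs = pm.cv_and_permute(conc, labels, positive_class="P",
                                       n_cv=15, n_perm=1, seed=s)
        diffs.append(obs - cv.mean())
    assert np.mean(diffs) > 0
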