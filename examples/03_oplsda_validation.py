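"""Fit and validate an OPLS-DA model on a simulated cohort.

One predictive + one orthogonal component on the Pareto-scaled relative
concentrations; quality is summarized by R2X/R2Y (explained variation)
and Q2 (7-fold cross-validated prediction), validated by a 100-label-
permutation test, and variable influence is scored by VIP.
"""

import psametab as pm

sc = pm.generate_cohort(seed=3)
rel = pm.relative_concentrations(sc.concentrations)
y = sc.cohort.group.to_numpy(str)

Xs, _ = pm.pareto_scale(rel.to_numpy(), columns=list(rel.columns))
model = pm.fit_oplsda(Xs, y, n_orthogonal=1, columns=list(rel.columns))
q2 = pm.cross_validate(rel.to_numpy(), y, n_orthogonal=1, folds=7)
print(f"1P + 1O model: R2X={model.R2X_cum:.3f} R2Y={model.R2Y_cum:.3f} "
      f"Q2={q2:.3f}  (Q2 > 0.5 indicates good prediction)")

perm = pm.permutation_test(rel.to_numpy(), y, n_perm=100, seed=3)
print(f"permutation test (100x): R2 intercept {perm.R2_intercept:.3f}, "
      f"Q2 intercept {perm.Q2_intercept:.3f}  "
      f"(Q2 intercept < 0.05 indicates a valid, non-overfitted model)")

v = pm.vip(model)
print("VIP > 1 metabolites (drivers of the class separation):")
print(v[v.selected].sort_values("vip", ascending=False).round(2))
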