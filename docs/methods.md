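# Methods

This note records the models, the defaults and the design decisions
behind each stage, what the synthetic data does and does not emulate, and
the numerical choices a maintainer would want to know.

## Synthetic cohorts

**What is emulated.** A two-group serum metabolomics study: `n_psa=29`
active psoriatic-arthritis patients and `n_hc=33` healthy controls, 13
metabolites (2-aminobutyrate … valine) whose per-group means and SDs are
the package defaults in `GroupParams.default()`, in relative-concentration
units (each group's 13 default means sum to ≈100, i.e. percent of total).
Concentration vectors are multivariate Gaussian with an exchangeable
metabolite-metabolite correlation (ρ = 0.1 by default — a mild positive
coupling typical of serum amino-acid panels; the reference cohort reports
no covariance information, so this is a package choice and is
configurable). Negative draws are handled by redrawing the whole sample
row rather than clipping, which preserves the group means; at the default
parameters the truncated mass is negligible (the most extreme margin,
patient methionine, sits 3.3 SD above zero).

**DAPSA.** The disease-activity score exists only for patients, is
strictly above the activity floor of 14, and has mean 25.2 / SD 10.4.
Naively truncating N(25.2, 10.4²) at 14 would bias the mean upward, so
the generator solves for the parent (μ, σ) of a left-truncated normal
whose *truncated* moments equal the targets. The solve is a
one-dimensional root-find on the standardized truncation point α (the
moment ratio (mean−floor)/sd is strictly decreasing in α), verified in
tests against `scipy.stats.truncnorm` closed-form moments.

**Metabolite–DAPSA coupling.** Target Spearman correlations (alanine
0.384, leucine 0.487 by default) are imposed through a Gaussian copula:
targets are converted to latent Pearson correlations via ρ = 2 sin(π r_s
/ 6) (exact for bivariate Gaussian copulas), a latent normal u is built
with those correlations to the linked metabolites' latent scores, and u
is quantile-mapped onto the truncated normal. Because the concentration
margins are (negligibly truncated) Gaussians, the standardized observed
columns serve as the latent scores — Pearson and Spearman correlations
are invariant to the affine standardization. The latent cross-correlation
among linked metabolites is estimated from the sample (the function does
not receive the generator parameters); the estimate is eigenvalue-floored
at 0.05 so tiny cohorts cannot produce spuriously infeasible systems,
while genuinely infeasible target combinations still raise an error
naming the metabolites. Note that the *sample* Spearman statistic at
n = 29 is slightly attenuated relative to the population value (by
roughly 0.015 at these targets); recovery tests budget for this.

**Spectra.** Each sample's spectrum is a sum of Lorentzian multiplets
(area ∝ concentration × proton-weighted relative area) on a 0.00–8.60
ppm axis, with per-sample, per-multiplet position jitter ~N(0, 0.005 ppm)
emulating pH-driven shift variation, a Gaussian residual-water band
centered at 4.95 ppm (SD 0.06 ppm, amplitude varying ±50 % per sample,
contained in the 4.70–5.20 ppm exclusion window), a TSP reference peak at
0.00 ppm, and additive Gaussian noise (SD 0.002). The chemical-shift
library is an editable YAML data file whose values follow standard
500 MHz serum compilations; the pipeline relies only on its internal
consistency, never on literature exactness. Not emulated: J-coupling
fine structure, field-strength dependence, T2 relaxation/line-shape
variation, baseline drift, macromolecule background. Passing tests
therefore demonstrate algorithmic correctness on idealized spectra, not
robustness to every artifact of real acquisitions.

## Bucketing

Nominal boundaries sit at region_start + k·0.04 ppm over 0.80–8.50 ppm.
Each relocatable interior boundary moves to the minimum of the reference
spectrum — the point-wise mean across samples, the deterministic standard
choice — within ± looseness·width/2 = ±0.01 ppm of its nominal position.
Argmin ties break toward the nominal position and a flat window keeps the
nominal boundary. Both edges of a bucket can each move 0.01 ppm, giving
the width guarantee [0.02, 0.06] ppm.

The region length 7.70 ppm is not a multiple of 0.04, leaving a 0.02 ppm
trailing remainder. Rule: a remainder ≥ width·(1−looseness) becomes its
own bucket with a *fixed* left boundary (the default case: a final
0.02 ppm bucket); a smaller remainder is merged into the previous bucket,
whose left boundary is then fixed. Either way every width stays provably
inside [0.02, 0.06] for any input — a relocatable boundary next to the
remainder could otherwise produce a 0.01 ppm bucket.

Bucket values are trapezoidal integrals over half-open [lo, hi)
intervals, computed from an exact piecewise-linear cumulative integral so
that bucket sums equal the quadrature total to 1e-9 relative even when
boundaries fall between grid points. Water exclusion removes any bucket
whose interval overlaps the open interval (4.70, 5.20) — the rule is
applied literally, so a bucket spanning the edge is dropped — after
integration and before total-area normalization (the upstream order).

## Scaling

Pareto scaling: center, then divide by √(sample SD, n−1 denominator —
the common chemometrics convention, configurable via `method=`).
Centering is applied even though "Pareto" names only the division, since
the latent-variable model requires it. Zero-variance columns map to
all-zero and are flagged; the stored model inverts the transform exactly
for unflagged columns.

## OPLS-DA

Two-class labels are coded as a single centered dummy column. With one
response column the NIPALS weight has the closed form w = X'y/‖X'y‖, so
the Trygg–Wold orthogonal-signal-correction iteration is deterministic:
per orthogonal component, w_o ∝ p − (w'p)w is normalized, its scores and
loadings deflated from X; then one predictive PLS component is fitted on
the filtered matrix. R²X accumulates the explained X-sum-of-squares of
predictive plus orthogonal components; R²Y is the explained dummy
variation.

Q² = 1 − PRESS/SS over k-fold cross-validation (default 7) with folds
assigned round-robin within class by input order — deterministic and
documented, in the spirit of every-Nth assignment; each training fold is
re-centered/re-scaled and its scaling applied to the held-out fold. The
permutation test refits model + CV on label-shuffled data, records
(|Pearson corr between permuted and original dummy|, R²Y, Q²) per
permutation plus the unpermuted model at correlation 1, and reports the
intercepts of unconstrained least-squares lines through all points
(the line is *not* forced through the unpermuted point; both choices
exist in the wild and this one is recorded in the output). Degenerate
permutation refits are skipped with a warning count.

VIP is the predictive-component variant (not total-model VIP; recorded
in the table's attrs): with one predictive component it reduces to
√p·|w_j|, so the mean squared VIP is identically 1 and VIP > 1 flags
above-average contributors.

Label-swap behaviour: reversing the class coding negates w and t while
the y-loading c is invariant, so predicted class-1 probabilities map to
their complement and R²/Q²/VIP are unchanged (property-tested).

## Univariate stage

Relative concentrations divide each sample row by its total and multiply
by 100, matching the scale of the generator defaults (the ×100
convention reproduces magnitudes like glucose ≈ 52). Because generated
rows sum to ≈100 but not exactly, renormalization nudges each entry by
the few-percent slack of the row total; the stage is exactly idempotent.
Mann-Whitney U uses midrank ties, exact enumeration when both groups
have n ≤ 8 and the pooled data are tie-free, otherwise the normal
approximation with tie and continuity corrections. Benjamini-Hochberg is
applied across the VIP-selected family only (mirroring the reporting
convention; configurable), and the significance flag requires raw
p < 0.05 *and* adjusted p ≤ 0.05 — inclusive, so an adjusted p printed
as exactly 0.05 counts.

## Biomarker panel

Logistic fits use IRLS with a tiny ridge (1e-8, intercept unpenalized)
for stability at n ≈ 60; complete separation is detected (all fitted
probabilities within 1e-6 of their labels) and reported while the
ridge-stabilized coefficients are still returned. The positive class
defaults to the healthy controls: evaluating the published coefficients
at the two group-mean vectors puts the HC vector at P ≈ 0.94 and the
patient vector at P ≈ 0.09 against the 0.38 cutoff, fixing the y = 1
coding; this arithmetic is frozen in the tests. Thresholds for newly fit
panels use Youden's J on the training ROC; the published 0.38 ships in
the fixture and is never re-derived silently.

ROC curves sweep all unique thresholds; the trapezoidal AUC equals the
midrank Mann-Whitney U/(n₁n₂) exactly (property-tested). The 95 % CI is
DeLong by default (placement-value variance), with a stratified
percentile bootstrap (2000 reps) as fallback for degenerate AUC ∈ {0,1}.
"100-fold cross-validation" is interpreted as 100 Monte-Carlo stratified
2:1 train/test splits — literal 100-fold is impossible at n = 62 — and
the permutation guard reports p = (1 + #{permuted resubstitution AUC ≥
observed})/(n_perm + 1), with floor 1/(n_perm+1).

## Clinical correlation

Spearman r is the Pearson correlation of midranks (the disease-activity
score is discrete-ish, so midranks matter). p is exact by full
enumeration of rank permutations for n ≤ 10 (chunked; 10! is the
practical limit) and the t-approximation with n−2 df above — the
asymptotic regime covers the n = 29 patient group. The CI is Fisher-z
with the 1.06/(n−3) variance inflation commonly used for Spearman's
statistic; how the reference CIs were computed is not documented, so
this choice is the package's own and its ~95 % coverage at n = 29,
ρ_s ≈ 0.49 is verified by simulation.

## Enrichment

Over-representation only (upper-tail hypergeometric), matching standard
metabolite-set ORA; BH across sets; ranking by raw p then enrichment
ratio k/(nK/N). The default universe is the union of the bundled
library's members (the metabolites the pipeline can see), configurable.
Query names missing from the universe raise an error listing them — no
silent dropping. Names are normalized by lowercasing, punctuation
stripping and an editable alias table. The bundled GMT is a small
curated library (~20 sets including the glucose-alanine cycle, glycine
and serine, glutathione, selenoamino acid, alanine and tryptophan
pathways) with literature-standard members, because the canonical SMPDB
library is not redistributable; pathway rankings on it are direction
checks, not reproductions of any external tool's output. The network
links sets with ≥ 1 shared universe member, edge-weighted by overlap,
nodes carrying enrichment ratio and p for the usual size/color encoding.

## Pipeline and reproducibility

`run_pipeline` chains simulate → (bucket → exclude → normalize) → Pareto
→ OPLS-DA (+ CV, permutation, VIP) → univariate on the VIP-selected set
→ panel + DAPSA correlation + enrichment on the significant set, and
writes every artifact with a sha256-checksummed manifest. Per-stage
seeds derive from the global seed XOR a CRC of the stage name (kept
below 2³¹), so stages re-run in isolation reproduce exactly. The
multivariate model in the default tabular pipeline runs on the 13
metabolite concentrations; when spectra are present the bucket matrix is
produced alongside for spectral-level modelling.

The package is a library: the importable API plus `examples/` scripts
are the interface, and no console command is installed — the pipeline
configuration object plays the role a CLI would.

## Problem sizes used in the shipped checks

Simulation-backed checks use 200 cohorts for the panel-AUC and
univariate summaries, 25 cohorts × 100 permutations for the
permutation-intercept summary, 1000 cohorts of n = 29 for copula
recovery, and n = 10 000 draws for generator calibration — sizes chosen
so Monte-Carlo error is comfortably inside each check's tolerance while
the whole suite stays desk-scale.

## Known limitations

- Idealized spectra (see above); bucketing robustness holds under the
  modeled jitter, not under strong baseline or line-width artifacts.
- Single predictive component / two classes only; no multi-class OPLS-DA,
  O2PLS or S-plots.
- The copula link between metabolites and disease activity is a
  phenomenological stand-in; whether real cohorts couple through disease
  severity or directly is not modeled.
- Exact reproduction of the reference study's model statistics (e.g.
  R²Y = 0.664, AUC = 0.842 on the real cohort) requires the unreleased
  patient data; simulation-based checks bound or bracket those values
  instead.
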