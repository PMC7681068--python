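# Methods

## Generative model of the synthetic cohort

The simulator emulates a SOMAscan-style plasma proteome: a subject ×
analyte matrix of strictly positive relative-fluorescence-unit (RFU)
intensities in which a known subset of analytes drifts linearly with age
on the log10 scale,

log10(x_ip) = mu_p + beta_p (age_i − a0) + gamma_p sex_i + eps_ip,
eps_ip ~ N(0, sigma_p²).

a0 is the **expected** mean of the age-sampling distribution (the
midpoint for uniform sampling), not the realized sample mean: this pins a
single generative line so that independent cohorts resampled from the
same ground truth (`resample_cohort`) are exchangeable with the original,
which the transfer and delta-age simulations rely on.

Default parameters (`CohortSpec`):

| parameter | default | meaning / rationale |
|---|---|---|
| `n_subjects` | 3000 | cohort of the scale used for clock building |
| `n_analytes` | 3000 | panel of the scale of a full SOMAscan run |
| `age_range` | (18, 76) y | adult donor range; uniform sampling by default (maximizes slope identifiability); a triangular option reproduces a blood-donor-like age profile with median 45 y |
| `frac_informative` | 0.15 | share of analytes with a true age trend (450 of 3000); `round()` fixes the exact count |
| `frac_increasing` | 0.7584 | share of informative slopes that are positive, matching the observed preponderance of proteins that rise with age |
| `beta_range` | [3.24e-4, 1.64e-2] per year | log-uniform slope magnitudes spanning the printed extremes of reported per-protein age coefficients |
| `noise_sd` | 0.05 log10 units | per-analyte residual scale; a calibration knob (no published per-analyte value exists), chosen so the full-panel clock reaches test r ≥ 0.9 at this cohort size |
| `sex_effect_sd` | 0 | sex offsets off by default — the default association model is age-only; switch on to exercise the sex covariate |
| `baseline_mean/sd` | 3.0 / 0.5 (log10) | baselines in the low thousands of RFU |

Intensities are exponentiated back to the raw scale, so the pipeline's
log10 transform is always well defined. One `numpy` Generator seeded from
`CohortSpec.seed` drives all draws; equal specs give bit-identical
cohorts.

What the generator does **not** model: SOMAscan hybridization noise
structure, batch/plate effects, heteroscedasticity, non-linear age
trajectories, analyte–analyte correlation beyond what the shared age
signal induces, and missingness. Passing tests therefore demonstrate the
statistical machinery under a clean linear signal, not robustness to
real-assay artifacts.

`inject_aging_shift` moves selected subjects along the aging axis by
adding `beta_p · delta_years` to every log10 value while leaving
chronological age untouched — the synthetic analog of a group whose
proteome is biologically older. `generate_pathway_collection` draws named
analyte sets, optionally enriched (80% of members by default) in truly
age-associated analytes.

## Age associations

Per-analyte OLS of log10 intensity on age (plus optional covariates from
the subject table) is vectorized through one shared design matrix; the
age slope's two-sided t p-value uses n − k residual degrees of freedom.
Constant analytes are reported with slope 0 and p = 1 and flagged rather
than raised, so a screen never dies on a degenerate column.
Benjamini–Hochberg is the default multiplicity correction (step-up,
clipped at 1); a Storey-style variant rescales BH by
pi0 = min(1, 2·mean(p > 0.5)). Direction calls (increasing / decreasing /
none) are made at q < 0.05 by default.

## Clock fitting

Inputs are z-scaled log10 intensities. Standardization means/sds
(ddof = 1) are computed on the **training split only** by default to keep
the test set untouched; `global_scaling=True` reproduces whole-cohort
scaling. Zero-variance analytes are dropped with a warning. The subject
split is a seeded uniform partition with |train| = round(2n/3).

The elastic-net objective (1/2n)‖y − b0 − Zb‖² + λ[(1−α)/2‖b‖² + α‖b‖₁]
is solved along a descending path of 100 log-spaced penalties from
λ_max = max_j |z_j'y| / (n · max(α, 0.001)) down to λ_max·10⁻⁴ (n > p) or
λ_max·10⁻² (n ≤ p). Tenfold CV with seeded fold assignment selects the
path value minimizing the mean of per-fold MSEs (lambda.min; ties go to
the larger penalty). Two solver routes give the same minimizer:

- **alpha = 0 (ridge):** exact solution from one thin SVD per fit,
  beta(λ) = V diag(d/(d² + nλ)) U'y. Per-fold factorizations are cached,
  so evaluating additional penalties is nearly free.
- **alpha > 0:** cyclic coordinate descent with warm starts. Full sweeps
  over all coordinates maintain the residual and detect entering/leaving
  features; between full sweeps the active set is converged with
  covariance (Gram) updates, inner products cached across the whole path,
  preceded by a direct solve of the fixed-sign active subproblem (made
  SPD by a 1e-8 diagonal jitter, reverted whenever it fails to decrease
  the objective). Convergence is declared only when a full sweep changes
  no coefficient by ≥ 1e-7; non-convergence raises, naming the penalty.

**Path extension.** The conventional pure-ridge path (mixing floor 0.001)
places all 100 penalties far above the CV optimum when the signal is
strong, leaving lambda.min stuck at the path boundary and the clock
visibly over-shrunk (prediction-on-age slope well below 1, inflated
MAE). Whenever the CV minimum falls on the smallest path value, the path
is therefore extended downward with the same log spacing — a decade at a
time for the SVD route, quarter-decades for coordinate descent (to avoid
descending needlessly into the saturated-LASSO regime) — until the
minimum is interior, up to four extra decades. The model records the
actual path used.

Evaluation reports Pearson r and the **median** absolute error in years.
A degenerate clock that predicts a constant (e.g. all weights zero at
λ_max) is assigned r = 0 so that screens can rank it sensibly.

## Pathway screen

GMT members may be analyte ids or gene symbols; symbols resolve through
the analyte annotations with a deterministic first-annotation-wins rule,
and unmapped members are dropped with a logged count. Pathways with fewer
than 2 mapped analytes (configurable) are excluded, and the exclusion
count is reported. All pathway clocks share one train/test split so
test-set metrics are comparable; a failing fit marks that pathway failed
instead of aborting the screen. Ranking is by test r (descending) or test
MAE (ascending) with ties broken toward fewer analytes, then pathway id.

## Transfer to reduced panels

`predict_with_subset` evaluates a clock using only the features a target
platform measures; omitting a standardized term is equivalent to imputing
the training mean, requires no target-cohort statistics, and attenuates
predictions toward the training mean age. The learning-set regression
predicted = a + b·age then gives κ = 1/b. Although a single "correction
coefficient" is quoted, the applied transform is the full affine
inversion (pred − a)/b — the unique map that restores slope 1 and
intercept 0 on the learning set; a bare-multiplier mode (κ·pred) is
available behind a flag. A learning-set slope within 1e-8 of zero raises
a degenerate-clock error.

## Delta age and group tests

Δ = predicted − chronological per subject; group summaries are
mean ± SD (ddof = 1). The default two-group test is the two-sample
Wilcoxon rank-sum — the statistically appropriate choice for independent
groups — with the paired signed-rank test available on request (it
requires equal group sizes and pairs subjects by stated order). Exact
null distributions are used up to a combined n of 25 when the data are
tie-free; otherwise the normal approximation with continuity and
mid-rank tie corrections applies. The report names the test that ran.

## Overrepresentation

Hypergeometric upper tail P(X ≥ k) per pathway with BH correction across
tested pathways, one-sided by design (the question is
overrepresentation). The default background is the measured panel — not
all protein-coding genes — because the panel is the artifact's universe;
outputs carry the background size used.

## Problem sizes used in the checks

The reference analyses behind this design were run on access-controlled
cohorts, so the test suite and `scripts/acceptance.py` measure
properties on synthetic data at desk scale: the headline clock runs at
the full default conditions (3000 × 3000, 450 informative, seed-driven);
FDR control uses 50 replicates of 1000 × 300 cohorts; the
accuracy-vs-panel-size check uses 800 × 400 cohorts with noise_sd = 0.3
(higher than default so test r has dynamic range across 10/50/200-feature
subsets instead of saturating near 1); transfer uses 600 × 200 cohorts
with a random 30% panel; delta-age power uses 400 × 200 cohorts with
24-subject groups and an injected 8-year shift. Exact small-sample
distributions are verified against exhaustive enumeration, the CD solver
against closed-form ridge and a 3-predictor grid-search oracle.

## Known limitations

- Linear, homoscedastic log10 trends only; no LOESS-style trajectories.
- No elastic-net mixing search: only α ∈ {0, 1} are exercised end to end.
- The simulator's independence of residuals makes clock accuracy
  optimistic relative to real plasma proteomes with correlated assays.
- The q-values of the original screening tool are not reproducible
  bit-for-bit; BH is used as the reproducible conservative default.
- Exact rank tests fall back to the normal approximation in the presence
  of ties, even at small n.
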