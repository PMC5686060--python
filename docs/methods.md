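# Methods

This note documents the models implemented in `msdss`, the choices made
where the design was genuinely open, and what the synthetic test bed does
and does not establish.

## Composite disability: CombiWISE

CombiWISE combines EDSS, SNRS and two timed tests into a continuous
0–100 score (coefficients in `msdss/scales.py`). Two conventions are ours:

* **Failed timed tests.** The composite's defining formula specifies a
  fail indicator (+18.056 for the walk, +10.751 for the peg test) but not
  the log term's argument when the test was failed. We evaluate the log
  term at the test ceiling (180 s / 300 s) *and* add the fail bonus. This
  makes the score continuous at the pass/fail boundary: a patient timed at
  exactly 180 s scores 18.056 less than one who just failed, rather than
  jumping by an arbitrary amount. A recorded time together with a fail
  flag is rejected as inconsistent.
* **Clipping.** Values outside [0, 100] (possible with double test
  failure at high EDSS) are clipped to the scale bounds and the event is
  logged.

## Rank-based severity: MSSS and ARMSS

Both scores rank a patient's EDSS within a reference distribution
conditioned on disease duration (MSSS) or age (ARMSS) and rescale to
(0, 10): `10 · rank / (N + 1)` with average tied ranks, the index patient
included in the pool when absent from it. The published global reference
tables are external artifacts; by default the reference is built
**locally** from the supplied cohort (first-visit EDSS, 1-year duration
bins or 5-year age bins, bins merged outward until each holds ≥5
patients). A user-supplied `ReferenceDistribution` can be passed instead
where the global tables are available. Local referencing changes absolute
score values but not their cohort-internal ordering, which is what the
correlation analyses use.

## Therapy-efficacy adjustment

Efficacy of a treatment epoch is the class line (low: `−1.50·ā + 83.71`
percent; high: `−4.34·ā + 206.39` percent) evaluated at the epoch's mean
age, divided by 100, clamped below at 0. Units are the one reading under
which `1 − Eff` is meaningful: the lines produce percent, all internal
arithmetic uses fractions.

The high-efficacy line exceeds 100% below roughly age 24.5, which would
make `1 − Eff` non-positive. We cap each epoch's fraction at a
configurable **0.95 before duration-weighting** (per-epoch rather than on
the cumulative value, so a short early-life epoch cannot dominate a long
window). Every cap and clamp event is logged.

Cumulative efficacy over a window is the duration-weighted mean of epoch
efficacies with epochs clipped to the window first and uncovered time
contributing zero. Slope adjustment uses the first-to-last retained visit
window; cross-sectional adjustment uses birth-to-visit, because disease
onset cannot be dated reliably. Worsening slopes divide by `1 − Eff`,
improving slopes multiply by it, zero is a fixed point; the adjusted value
therefore never falls below the measurement, with equality exactly at
zero efficacy.

## Progression slopes

Exacerbation-flagged visits are removed before anything else (their
disability is largely transient), then eligibility is assessed (≥3 usable
visits spanning ≥1 y, or ≥2 spanning ≥3 y) and a per-patient OLS of scale
value against age is fit over the retained visits, including baseline.
R² is reported only when residual variation is defined — at least three
points and a nonconstant response; patients with undefined R² on either
scale are excluded from the paired CombiWISE-vs-EDSS R² comparison and
logged. No robust or mixed-effects estimation is attempted: the method is
deliberately per-patient simple linear regression.

## Partitioning

The 2:1 training/validation split stratifies on race, sex, and
above/below-median therapy-adjusted CombiWISE/age and age at first visit.
Crossing four binary variables yields **16** cells; we implement the full
crossing (empty cells skipped) and do not attempt to force any smaller
grouping count. Ties at a median go to the lower bin (configurable).
Within each cell, `round(2n/3)` patients (half-up) are drawn without
replacement into training. `partition_stability` instead uses fully
random splits, retrains the model per replicate, and summarizes the
validation Pearson correlations; replicates with an undefined correlation
contribute 0 and are counted separately from hard failures, which are
dropped and reported.

## The severity model

Thirteen candidate features are built from first-visit (or, configurably,
last-visit) data: therapy-adjusted CombiWISE/age, measured CombiWISE,
COMRIS-CTD, onset-to-first-therapy delay, adjusted-minus-measured
CombiWISE, age, family history (ordinal 0–3), sex, race, smoking, number
of DMT epochs shorter than 6 months, cumulative follow-up efficacy, and
therapy type (none/low-only/high-only/both). Missing values (COMRIS-CTD,
delay for never-treated patients, unknown family history) propagate as
NaN out of feature construction.

The regressor is scikit-learn's `GradientBoostingRegressor` — the classic
stagewise Friedman GBM, matching the algorithm family the method was
designed around — with interaction depth 2, shrinkage 0.001, half-sample
bagging per tree, a minimum terminal-node size of 10 (the reference R
implementation's default; without it, depth-2 trees on ~130 patients
overfit through single-observation leaves), and the number of trees
selected by 5-fold cross-validation over a multiplicative grid
(100–20,000 by default). Because this learner rejects NaN, missing values
are handled by a **missingness indicator plus median imputation**
immediately before the learner; the strategy is recorded in the model
metadata and indicator-column influence is folded back into the parent
feature.

Relative influence is the per-feature share of total squared-error split
improvement across the ensemble, normalized to 100. The reduced model
retrains on exactly the features above the 4.0% threshold. A
constant-target fit degenerates to a constant predictor with zero
influence everywhere (no split can improve the error), which is reported
as such rather than renormalized.

MS-DSS is reported in predicted therapy-adjusted CombiWISE units/year —
the regression target's natural units; no rescaling to a 0–10 convention
is applied because none is defined for it.

## Synthetic cohort: study conditions

The generator emulates the cohort the pipeline expects, with marginals
calibrated to the reference cohort's summary statistics: first-visit age
48.6 ± 11.6 y (truncated 23–70), onset 37.1 ± 11.4 y (≥8, before first
visit), untreated baseline CombiWISE 30.4 ± 17.5, COMRIS-CTD 12.8 ± 6.3,
follow-up span 4.49 ± 2.90 y (truncated 1–12), ~1.5 visits/year, ~50%
female, ~88% white, ~60% smokers, family-history categories at their
published proportions. Because truncation shrinks dispersion, the
pre-truncation (μ, σ) are solved numerically so the *truncated* moments
hit the targets.

The true untreated slope (CombiWISE units/year, mean 1.0, ~15% of
patients improving via shifted-gamma noise) couples to:

* standardized untreated baseline CombiWISE/age, coefficient 1.0,
  **saturating beyond ~1.25 SD** (progression rates plateau at high
  disability, consistent with the observed flattening of accrual at
  higher EDSS);
* standardized COMRIS-CTD, coefficient 0.4, with COMRIS correlated 0.35
  with baseline disability (the modest clinico-radiological concordance);
* a step of 0.35 units/year when therapy started more than 6 years after
  onset or never (delayed treatment lets compartmentalized inflammation
  establish; the effect saturates rather than growing linearly).

Treatment history embodies **confounding by indication**: the probability
of pre-visit treatment (baseline 0.5) rises with severity (+1 logit per
SD of baseline CombiWISE/age), treated patients start after an
exponential delay (mean 3 y) and then stay on therapy up to the visit
apart from short switching gaps, occasionally preceded by an abandoned
<6-month trial. This is what makes therapy adjustment informative: in the
treated (sicker) patients, measured disability understates severity by
exactly the efficacy factor the adjustment removes. Follow-up treatment
is assigned independently (45% none, 20% low, 20% high, 15% both).

The forward model is the exact inverse of the adjustment calculus: the
measured baseline is `untreated · (1 − Eff(0, t₀))`, and each treated
follow-up segment progresses at `true · (1 − Eff)` (worsening) or
`true / (1 − Eff)` (improving). Visit-level CombiWISE adds Gaussian noise
(sd 2 units) and a +8 transient bump at exacerbation visits (5% of
visits), then is decomposed into an (EDSS, SNRS, T25FW, 9HPT) quadruple
that reproduces the emitted composite to machine precision — EDSS drawn
on its legal grid near composite/10, SNRS near its anti-correlated
integer value, the timed tests solving the remainder exactly.

What the generator does **not** emulate: failed timed tests (the
decomposition stays exactly solvable without them; the fail convention is
unit-tested directly), relapsing–remitting biology beyond the
exacerbation bump, visit-level COMRIS dynamics (constant per patient),
MRI rating itself (COMRIS-CTD is consumed as a number), and any
real-data deviation from the assumed piecewise-linear latent trajectory.
Passing the simulation experiments therefore shows the pipeline is
*internally consistent* and recovers known structure under its own model
assumptions — not that real cohorts satisfy those assumptions.

## Problem sizes and fast settings

Simulation experiments (`scale_experiment`, the stability analysis, the
acceptance script) use a GBM profile of shrinkage 0.02 with a 500–2,000
tree grid (and a fixed 400-tree, shrinkage-0.01 fit inside the stability
replicates). Pearson correlation is invariant to the prediction scale, so
partially converged boosting preserves correlation orderings while
keeping a 20-cohort replicate run in minutes; the headline configuration
(shrinkage 0.001, grid to 20,000) remains the default of `train()`. The
repeated-partition stability analysis runs 100 replicates by default, a
scaled-down version of the full 5,000-partition design. The reference
cohort size is 201 patients throughout.

## Numerical notes

* CSVs are read with `float_precision="round_trip"`; the default pandas
  float parser is not correctly rounded and breaks write/read identity.
* Epoch splitting changes cumulative efficacy only through the mean-age
  discretization of each sub-epoch; for an age-flat efficacy model it is
  exactly invariant (tested).
* Constancy of a prediction vector is detected with `np.ptp == 0`
  (exact), not a standard-deviation comparison.
* The slope branch at exactly zero measured slope returns zero, the
  common limit of both adjustment branches.
* Seeds: every stochastic routine takes an explicit seed; cohort
  generation, splitting, training and the stability analysis are
  deterministic given it.
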