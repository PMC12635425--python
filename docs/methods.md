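# Methods

This note documents the model underlying `grscreen`, the defaults it ships
with, the numerical choices, and what the synthetic data generator does and
does not emulate.

## The GR transform and why it is used

End-point viability ratios confound drug effect with division rate: a
slowly dividing culture looks "resistant" simply because the control barely
grew. The growth-rate-inhibition value removes that confound. With `x0` the
mean ATP signal at treatment start, `x_ctrl` the mean end-of-treatment
negative-control signal and `x(c)` the treated signal,

    GR(c) = 2^( log2(x(c)/x0) / log2(x_ctrl/x0) ) − 1 .

Under exponential growth the exponent is the ratio of treated to control
division rates, so GR is invariant to seeding density, assay duration and
the organoid's intrinsic growth speed. GR = 1 means no effect, 0 complete
cytostasis, −1 complete kill; GR is undefined when the control fails to
grow (`x_ctrl ≤ x0`), which the package treats as a hard error rather than
guessing. Treated wells reading ≤ 0 are clamped to a small positive floor
(10⁻⁶ · x0) and flagged.

## Two-step screening design

**Preliminary stage.** Single dose per drug at the clinical maximum plasma
concentration (Cmax), endpoint-only (no start read; GR is not computed at
this stage). Viability is the ratio of treated to NC mean signal with
arithmetic-mean replicate aggregation and no outlier rejection. Candidate
selection keeps drugs with viability ≤ 0.20 — the boundary is inclusive and
compared without rounding — sorted ascending by viability and truncated at
three; ties are broken by drug-registry order (flag `tie-truncated`), and
an empty qualifying set is flagged `no-candidate`. Cisplatin and paclitaxel
are always carried into the secondary screen regardless of their
preliminary viability, because the patient-level score is defined on them.

**Secondary stage.** Six-point fourfold titrations (per-drug top doses from
the packaged registry), triplicate wells, paired start/end ATP reads.
Replicate GR values are averaged per concentration before fitting, with
uniform weights.

## Curve fitting and derived metrics

The GR sigmoid `GR(c) = GR_inf + (1 − GR_inf)/(1 + (c/GEC50)^h)` is fitted
by bounded least squares on log₁₀ concentration (GR_inf ∈ [−1, 1], log₁₀
GEC50 within the tested range ± 4 decades, h ∈ [0.05, 10]). Local minima
are handled with a deterministic multi-start grid over the Hill slope
(0.5, 1, 2, 4) and midpoint inits (mean/min/max of the tested log-range),
with an early exit once a start reaches an essentially exact fit. A fit is
reported `converged` only when the optimiser succeeds *and* the observed
mean-GR dynamic range is at least 0.1 — flatter profiles cannot constrain a
sigmoid, so an inert drug deliberately falls back to a flat model
(`GR_inf` = mean GR, `converged = False`) instead of a spurious fit.

* **GRmax** is the minimum *observed* mean GR across tested doses, not the
  fitted asymptote — robust to extrapolation of `GR_inf`.
* **GR50 / GR100** are the closed-form roots of the fitted sigmoid at
  GR = 0.5 / 0. GR100 — the dose achieving complete growth-rate
  inhibition — is a concentration, directly comparable with Cmax; that is
  what makes the decision rule "GR100 > Cmax ⇒ resistant" dimensionally
  meaningful. When the asymptote never reaches the level, the metric is
  absent (treated as +∞ downstream). When the fit did not converge but the
  measured points bracket the level, a log-linear interpolation between the
  bracketing doses is used (flag `interpolated`). Crossings outside the
  tested dose range are still reported — suppressing them would break the
  Cmax/GR100 ranking for very potent drugs, whose crossings legitimately
  sit far below the lowest tested dose — but are flagged `extrapolated`,
  with a warning once they are more than one dilution step outside.
* **Normalized AUC** integrates the *raw* mean viability fractions (not the
  fitted curve) over log₁₀ dose by the trapezoid rule and divides by the
  maximal possible area, giving a value in [0, 1] that is invariant to dose
  ordering; inputs outside [0, 1] are clipped with a warning. A constrained
  log-logistic viability fit (top 100 %, bottom 0 %, free EC50 and slope)
  is provided for reporting and plots only.
* **AUCsum** = cisplatin + paclitaxel normalized AUCs ∈ [0, 2]. Both drugs
  are mandatory in the secondary screen; a missing one is an error, not a
  silently partial score.

## Decision rules

* **AUCsum call**: predicted TP-resistant iff AUCsum > 1.134 (the packaged
  default threshold); equality falls on the sensitive side — the boundary
  itself carries no evidence either way, and a fixed convention keeps the
  classifier deterministic. The concordance module offers a Youden-based
  data-driven threshold for users who want to re-derive a cutoff on their
  own cohort, but the default constant is not recomputed.
* **Per-drug tree**: RESISTANT iff GR100 > Cmax (including GR100 absent);
  SENSITIVE iff GR100 < Cmax and GRmax < −0.5; PARTIAL otherwise, including
  GR100 = Cmax exactly. The three branches partition the metric space
  (property-tested by brute force).
* **Alternative ranking**: descending Cmax/GR100, ties broken by registry
  order (flag `tied-ranking`); Cmax/GR100 is defined as 0 when GR100 is
  absent — a drug that never halts net growth at any dose cannot be
  recommended — and an all-zero ranking is flagged `no-effective-agent`.

## Concordance statistics

The positive class is *clinically good responder, predicted sensitive*:
sensitivity = recall on good responders, specificity = recall on poor
responders. This orientation is a documented choice (the mirrored
statistics are also exposed). Histological regression grades map 2/3 →
GOOD, 0/1a/1b → POOR; treatment-naive patients carry a binary follow-up
label directly; records without an outcome are excluded and tallied. ROC
AUC is computed on the continuous AUCsum (sign-flipped so low AUCsum argues
for a good response) with the rank statistic (ties ½), cross-checked in the
tests against an all-pairs oracle. The Youden scan evaluates midpoints of
adjacent sorted unique scores and resolves ties toward the smaller
threshold.

## Synthetic data generator

The generator is the exact inverse of the GR model: control division rate
`k0` (doublings/day), treated rate `k(c) = k0 · log2(GR_true(c) + 1)`,
signal `x(c) = x0 · 2^(k(c)·T)` over a `T = 4`-day window, triplicate
wells, mean-one multiplicative lognormal noise with CV 0.08 by default (the
order of replicate dispersion typical of ATP luminescence assays;
user-configurable, not claimed to match any particular instrument).
`GR_true + 1` is floored at 10⁻¹² so complete-kill simulations stay
strictly positive. With zero noise the full pipeline recovers the true
sigmoid parameters and latent classes exactly, which the test suite uses as
its strongest end-to-end oracle.

Cohort defaults: 24 patients, 14/24 latently TP-resistant, clinical label
flipped with probability 1/6 — the scale and discordance rate of the kind
of perioperative-chemotherapy cohort the method targets. Resistant
organoids draw TP parameters from a weak-effect regime (GR_inf ∈ [−0.1,
0.3], GEC50 10–100 × Cmax), sensitive ones from a strong-effect regime
(GR_inf ∈ [−1, −0.6], GEC50 0.01–0.1 × Cmax); non-TP drugs draw generic
parameters (GEC50 log-uniform 0.01–100 µM, h ∈ [0.5, 4], GR_inf ∈ [−1,
0.5]). All randomness flows through one seed; equal seeds give
byte-identical CSV outputs.

What the generator does **not** emulate: spatial plate effects and
evaporation gradients, drug degradation and pharmacokinetic time-courses,
non-exponential (e.g. contact-inhibited) growth, heteroscedastic
count-dependent noise, and any tumour-microenvironment contribution to
clinical response beyond the flat label-flip probability. Passing tests
therefore demonstrate correctness of the *analysis* under the stated
generative assumptions, not predictive performance on real organoid data.

## Problem sizes used in checks

The acceptance script runs 200 noiseless recovery curves, a 16-patient
noiseless cohort for class recovery and one 24-patient noisy cohort through
the full pipeline — sizes chosen to match a realistic cohort while
keeping a complete from-scratch rerun under a minute on one CPU.

## Known limitations

* The AUCsum threshold and GRmax cutoff are taken as fixed constants;
  their transferability across tumour types or assay protocols is not
  established, and the Youden scan is provided for local recalibration.
* AUCsum treats the two TP drugs additively; synergy or antagonism is out
  of scope.
* GR requires a growing control; assays where organoids are quiescent over
  the window cannot be scored (hard error by design).
* Fits with fewer than four distinct concentrations are refused rather
  than attempted.
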