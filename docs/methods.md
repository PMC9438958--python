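# Methods

## Data model and conventions

Observed data are right-censored pairs (T_i, Δ_i) with T_i = min(Y_i, C_i)
the observed time and Δ_i = 1 when the event was seen. Curve predictions
are an M × K matrix of survival probabilities over a shared, strictly
increasing positive grid. Every curve is treated as a right-continuous
step function: S = 1 strictly before the first grid point, the value at
the largest grid time ≤ t inside the grid, and the last value carried
forward beyond it. This matches the product-limit estimator's own
definition (S = 1 for t < t₍₁₎) and makes all downstream measures
well-defined at arbitrary evaluation times. t = 0 is deliberately not a
grid point; the step convention supplies S(0) = 1.

Times are unitless reals. Subject alignment between files is always an id
join; a mismatch is an error, never a silent reindex. Risk vectors obey
one orientation contract everywhere: strictly larger risk = strictly
higher predicted hazard. Reductions of survival-probability or
survival-time summaries are therefore negated, and every risk vector
carries a label naming its provenance.

## Kaplan–Meier estimation

`kaplan_meier` implements the product-limit estimator over distinct event
times with the standard tie convention: at a time carrying both events and
censorings, the censored subjects still count as at risk for the event
(events before censorings). `censoring_km` is exactly the same estimator
with the status flipped, giving the censoring survival G used as the IPCW
denominator. With every observation censored the event grid would be
empty, so the grid collapses to the largest observed time with S ≡ 1.
When the largest observed time is censored the estimate plateaus above
zero — an *improper* predicted distribution, the central pathology the
reduction policies address.

## Concordance estimators

Comparable pairs are ordered pairs with T_i < T_j and Δ_i = 1; tied
outcome times are never comparable (strict inequality, including
event–event ties — some other implementations differ). Risk ties receive
½ credit, which is what puts a fully tied risk vector exactly on the 0.5
floor. Two +∞ risks (curves that hit zero survival) compare as a tie.

Uno's C weights each comparable pair with T_i < τ by G(T_i⁻)⁻², using the
left limit so a subject's own censoring step cannot zero its weight. τ
defaults to the largest observed event time. A pair whose weight
denominator is 0 is an error instructing a smaller τ, not a silent drop.
With no censoring G ≡ 1 and the value equals Harrell's C exactly.

Antolini's C compares S_i(T_i) against S_j(T_i) per comparable pair via
the step convention, with ½ credit on ties. A consequence worth knowing:
if the prediction grid starts after some observed event times, those
pairs compare 1 against 1 and tie, dragging the value toward 0.5 — the
mechanism by which the time-dependent index can fall below Harrell's C on
otherwise perfectly ordered proportional-hazards predictions. It is
exposed only for curve matrices; risk vectors are refused, since the
measure is defined on distributions.

The cumulative/dynamic AUC at cutoff t is the plain empirical rank
statistic over cases (T_i ≤ t, Δ_i = 1) and controls (T_j > t) — the
Mann–Whitney form of the integral of the time-dependent ROC curve — not a
smoothed or IPCW variant; the estimator is named in the result label. The
concordance-from-AUC integral uses the *incident*/dynamic AUC (cases
failing exactly at t) weighted by the Kaplan–Meier plug-in w(t) ∝
2·f̂(t)·Ŝ(t) normalised to 1: that is the weighting under which the
identity C = ∫ 2 f S AUC dt actually holds. On uncensored data the
weights reduce to comparable-pair counts and the integral equals
Harrell's C to floating-point accuracy; integrating the cumulative AUC
instead would overshoot concordance substantially (we measured ≈ +0.07 on
an uncensored n = 500 cohort), so that construction is not offered.

## Reductions and improper-curve policies

The discrete distribution implied by a curve places mass
S(t_{k−1}) − S(t_k) at t_k (S = 1 before the grid).

- **Mean.** The unnormalised sum Σ_k t_k·mass_k. For a proper curve this
  is the distribution mean; for an improper curve under the `naive`
  policy part of the mass is missing and the sum is biased low — and, on
  heavily truncated windows where within-window mass grows with true
  risk, the ranking *inverts* (concordance below 0.5, the exact
  complement of the true value in the strict-PH case). The unnormalised
  definition is chosen deliberately: it is the discrete mean consistent
  with the observed pathology of "absurdly low" naive summaries; a
  normalised mean would not misbehave and would not reproduce it.
- **Median.** The smallest grid time with S ≤ 0.5. Under `naive` it is
  undefined for a curve that never reaches 0.5; this raises an error
  naming the rows rather than imputing anything.
- **Drop policy.** Appends one grid point at (last time + offset) with
  S = 0, placing all remaining mass there; offset defaults to the
  smallest grid spacing. Already-proper rows are unchanged in
  distribution. This assumes everyone alive at the study end dies at
  once, skewing summaries toward the final time.
- **Linear policy.** Extends each row along the line through (0, 1) and
  its last point to the zero crossing t_K/(1 − S(t_K)), discretised at
  the grid's median spacing with each row's crossing included. Shallow
  curves produce very distant crossings (a curve ending at 0.81 at
  t = 104 reaches zero only at ≈ 547), illustrating why extrapolated
  summaries can be unrealistic. A row ending at exactly 1 has no
  crossing and is refused. Neither policy ever modifies a pre-existing
  grid point.
- **Expected mortality.** Σ_t −log S(t) over the grid. −log 0 = +∞ is
  propagated, not clamped; concordance treats two infinities as a tie
  and a warning notes when that happens. The quantity depends on the
  grid only through which points are included, and any pointwise-
  dominated curve gets strictly smaller φ, so on non-crossing
  proportional-hazards curves it reproduces the linear-predictor ranking
  exactly.

## Synthetic cohorts

The generator emulates the standard Weibull proportional-hazards setup:
X ~ N(0, I_p), η = Xβ, baseline survival S₀(t) = exp(−(t/λ)^k), event
times by inversion Y = λ(−log U / e^η)^{1/k}, independent exponential
censoring (independence is required by the measures' assumptions; the
default rate is 0 so properties are tested without censoring noise
unless a test asks for it). Defaults n = 300, β = (1), k = 1.5, λ = 10,
grid of 50 points spanning the 1st–99th percentile of the baseline
distribution — a moderately discriminating single-marker cohort
(C ≈ 0.7) of the size typical for methodological illustrations.

Because the model is strictly PH, true curves never cross, so
probability-at-a-time, the proper-curve mean, expected mortality and
Antolini's comparison all recover the η ordering exactly; the test
suites assert bit-identical concordances across these routes, and obtain
improper fixtures by truncating the true curves inside the observation
window. What the generator does *not* emulate: crossing hazards,
covariate-dependent censoring, tied recorded times, model misfit —
passing tests show the measures' internal consistency, not robustness of
any fitted model on real registries. One classic real dataset (the
300-subject rat carcinogenicity study bundled with the R `survival`
package) is pulled in at test time purely to check the Kaplan–Meier
plateau of an improper distribution (0.81 at t = 104).

## Reporting layer

A plan (YAML) declares models with their prediction kind, the measure ×
transformation rows, and exactly one primary measure; its SHA-256 digest
is computed before evaluation and stamped on the report. Compatibility
is structural: time-independent measures touch risk models only natively
and curve models only through a named reduction; Antolini touches curve
models only. An incompatible cell renders as "—"; a plan none of whose
models can ever satisfy a requested row is rejected outright as
incommensurable. All planned cells are computed and reported — there is
no path that drops an unflattering number — and ranked comparisons
across rows with different measures or transformations are refused.
Values render to 3 decimals in text/markdown and full precision in CSV;
ad-hoc runs are possible only behind an `--exploratory` flag that stamps
every output line.

## Numerical choices and problem sizes

All estimators are exact finite-sample computations (no smoothing, no
tolerance parameters); equality-sensitive tests therefore assert exact
or 1e-12-level agreement. Property and oracle tests run on ~100 random
instances of n ≤ 30 against explicit-loop references, plus cross-checks
against lifelines (Kaplan–Meier, Harrell) and scikit-survival (IPCW
concordance, cumulative/dynamic AUC). Cohort-level checks use n = 300
(consistency suite) and n = 500 (AUC-integral collapse), sizes at which
every suite completes in seconds.

## Known limitations

No confidence intervals or tests for C differences; no competing risks,
left truncation or interval censoring; no calibration measures or proper
scoring rules — discrimination only; no parametric tail extension beyond
the two extrapolation policies; reductions apply one policy to all rows.
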