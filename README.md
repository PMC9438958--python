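# survdisc

Discrimination measures for survival-model predictions — with the
transformations made explicit, so that no concordance number can be quoted
without saying how it was computed.

## The problem

Survival models predict the time until an event in one of two shapes: a
single **relative risk** φ per subject, or a whole **survival curve**
S(t) per subject (a matrix S ∈ [0,1]^{M×K} over a shared time grid).
Discrimination is almost always summarised by a concordance index — the
probability that, for a comparable pair of subjects (T_i < T_j, event of
*i* observed), the predictions order the pair the same way as the
outcomes:

    C = P(φ_i > φ_j | T_i < T_j, Δ_i = 1)

But a curve is not a risk. To evaluate a curve-predicting model (a random
survival forest, a Cox model's `survfit` output, a neural survival model)
with a risk-based index you must first *reduce* the curve to a number, and
the choice of reduction can move "the C-index" from 0.86 to 0.14 on the
same predictions. Quoting the favourable variant, pooling structurally
different indices into one column, or omitting the reduction entirely is
**C-hacking**. This package computes every variant and refuses to let any
of them travel unlabelled.

## What it implements

**Measures**

- Harrell's C — unweighted concordance over comparable pairs, risk ties ½.
- Uno's C — IPCW concordance: each pair weighted by G(T_i⁻)^{-2}, with G
  the Kaplan–Meier estimate of the censoring survival function; collapses
  exactly to Harrell's C when nothing is censored.
- Antolini's C — time-dependent concordance directly on curve matrices:
  a pair is concordant when S_i(T_i) < S_j(T_i). Applies *only* to
  distribution predictions.
- Cumulative/dynamic AUC(t) and its Kaplan–Meier-weighted integral
  (weights ∝ 2·f̂(t)·Ŝ(t)), a concordance estimate from the ROC family.

**Distribution → risk reductions** (each returns a labelled risk vector)

- `prob_at_time`: φ = −S(t′) at a chosen time t′.
- `curve_summary`: φ = −mean or −median of the discrete distribution
  implied by the curve, with an explicit policy for *improper* curves
  (curves that plateau above 0): `naive` (no fix — the mean becomes an
  unnormalised truncated sum and can invert the ranking), `drop` (force
  S → 0 just after the study end), `linear` (extend the line through
  (0, 1) and the last point to its zero crossing).
- `expected_mortality`: φ = Σ_t −log S(t), the sum of the predicted
  cumulative hazard — assumption-free and robust to improperness.

**Reporting layer** — a pre-registered evaluation plan (YAML) fixes the
models, measures and transformations before any number is computed; the
report carries the plan's SHA-256 digest, marks the declared primary
measure, renders incompatible measure/model cells as "—", and refuses
ranked comparisons across different measures or transformations.

**Synthetic cohorts** — a Weibull proportional-hazards generator with
known linear predictors η and exact survival curves, so every property
above can be tested against ground truth with no external data.

## Worked example

```
$ survdisc simulate --n 200 --beta 1.5 --censor-rate 0.05 --seed 7 --outdir .
wrote cohort of 200 subjects (127 events) to ./

$ survdisc concordance --measure harrell --risk risks.csv --outcomes outcomes.csv
Harrell's C [risk:risks.csv] = 0.760 (10034/13208 pairs)

$ survdisc reduce --method expmort --curves curves.csv --out expmort.csv
wrote 200 risks [ExpMort] to expmort.csv

$ survdisc evaluate --plan plan.yaml --outcomes outcomes.csv --out report.json
Measure       Type  Trafo               cph    rsf
Harrell's C*  TI    —                   0.760  —
Uno's C       TI    —                   0.757  —
Antolini's C  TD    —                   —      0.761
Harrell's C   TI    ExpMort             —      0.760
Harrell's C   TI    Summary(mean,drop)  —      0.760

plan sha256:d7531a81c121e7cb
```

Reading the table: the `cph` model supplied native risks, so only the
time-independent indices apply to it without a transformation; the `rsf`
model supplied curves, so Harrell's C applies only through a *named*
reduction (here expected mortality and the drop-extrapolated mean —
which agree, because these curves are order-preserving in the true risk).
Antolini's C evaluates the curves directly; its 0.761 lives in a
different row and is never pooled with the risk-based 0.760. The `*`
marks the measure declared primary in `plan.yaml` before the run, and
the footer digest proves the plan was not edited afterwards.

The plan file:

```yaml
models:
  - {name: cph, kind: risk, file: risks.csv}
  - {name: rsf, kind: distribution, file: curves.csv}
measures:
  - {measure: harrell, primary: true}
  - {measure: uno}
  - {measure: antolini}
  - {measure: harrell, transform: expmort}
  - {measure: harrell, transform: mean, improper: drop}
```

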