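# Methods

## The aggregation problem

A crowd of forecasters each reports, for every binary event (a statement
that is either true or false), a probability forecast `P_i ∈ [0, 1]` and a
meta-prediction `M_i ∈ [0, 1]` — their estimate of the average probability
the *other* forecasters will report. The task is to combine these into a
single probability per event that scores well under a strictly proper rule,
when nothing is known about any forecaster's track record.

## Aggregators

**Simple average** `T_µ = mean(P)` — the baseline; optimal when everyone is
equally informed, conservative otherwise.

**Minimal pivoting** `T_MP = mean(P) + (mean(P) − mean(M)) =
2·mean(P) − mean(M)` — corrects the crowd mean for shared information by
pushing it away from the mean meta-prediction. The raw value can leave
[0, 1]; we clamp before scoring or extremising, since both downstream
operations are defined on probabilities. (Whether to clamp before or after
extremising is an open choice; extremising an out-of-range value is
undefined, so clamping first is the only coherent order.)

**Meta-probability weighting (MPW)** `T_MPW = Σ W_i P_i` with
`W_i = |P_i − M_i| / Σ_j |P_j − M_j|`. Weights are nonnegative and sum to
one, so the aggregate is a convex combination of the individual forecasts.
If every forecaster's gap is zero the weights are undefined; we fall back to
uniform weights (the simple average) and flag the event. The rationale comes
from the signal model below: a forecaster whose report equals their
meta-prediction carries no private information beyond the common prior, and
with no informative member the crowd mean is the least-assumption default.

**Mean individual** — not an aggregator but a benchmark: the average of the
individuals' own scores, computed within each event first so that per-event
pairing with the aggregators is well defined (forecasters answer different
subsets of the questions, so per-forecaster averaging would break pairing).

## Extremisation

Averaged probability forecasts are systematically under-confident;
the recalibration transform

```
t(p) = p^a / (p^a + (1 − p)^a)
```

acts linearly in log-odds space (`logit t = a·logit p`), extremising for
`a > 1` and anti-extremising for `0 < a < 1`. The reproduction default is
`a = 2.5`, a value established in advance by large-scale geopolitical
forecasting calibration studies — it is not fitted to any dataset here. The
transform is applied to the *aggregate* for simple average, MPW and minimal
pivoting, and to each *individual* forecast for the mean-individual
benchmark (there is no aggregate to transform).

`a = 0` is admitted because the recalibration grid starts at 0. We take the
`a → 0+` limit: interior probabilities collapse to 1/2 while the endpoints
0 and 1 — fixed points for every positive `a` — stay fixed. `a < 0` is
rejected.

## Scoring

Transformed Brier score per event: `s_k = 100 − 100·(D_k − T_k)²`, with
`D_k ∈ {0, 1}` the outcome; a method's score is the mean over events. This
is an affine transform of the raw Brier score, hence strictly proper; 100 is
a perfect forecast, 0 the worst possible. Per-difficulty summaries treat
each tier's question set as its own dataset.

## BCa bootstrap inference

Comparisons are paired per-event score differences; the resampling unit is
the event. For `B` bootstrap resamples of the mean difference:

* bias correction `z₀ = Φ⁻¹[(#{boot < obs} + ½·#{boot = obs}) / B]` — ties
  counted half, because tied resample means are plausible with discrete
  scores; the fraction is clipped to `[1/2B, 1 − 1/2B]` to keep `z₀` finite;
* acceleration `â = Σu³ / (6(Σu²)^{3/2})` from the leave-one-event-out
  jackknife deviations `u_i = mean(jack) − jack_i`;
* interval endpoints are the bootstrap quantiles (linear interpolation) at
  `Φ(z₀ + (z₀ + z_α)/(1 − â(z₀ + z_α)))`.

With `z₀ = â = 0` this is the percentile interval, which the tests force on
symmetric data. All-identical differences yield a degenerate `[d, d]`
interval with a warning rather than an error, so method-vs-itself
comparisons stay well defined. A single seeded generator drives all
resampling; results are bit-reproducible given `(seed, n_boot)`, and
reversing a comparison exactly negates the mean and reflects the interval.
Defaults: `n_boot = 10 000`, 95% level, significance = interval excludes 0.
Strata with fewer than two paired events are skipped with a warning (a
one-event stratum cannot be resampled meaningfully).

No multiple-testing correction is applied across the pairwise comparisons;
significance flags are per-comparison CI-excludes-zero statements.

## Leave-one-out recalibration

For each held-out event `k`, the grid value `a_k ∈ {0, 0.01, …, 10}`
maximizing the mean transformed Brier of the extremised standard aggregates
over the other `K − 1` events is selected; the held-out forecast is
`t(aggregate_k, a_k)`. Ties break toward the smallest `a` (the least
aggressive transform; deterministic). The held-out outcome never enters the
selection — a test perturbs it and asserts `a_k` is unchanged. In
reproduction mode the MPW reference stays at the fixed `a = 2.5` while the
comparators are recalibrated, which is the conservative comparison: the
reference gets no benefit of per-question tuning.

Parameter recovery: when data are generated so that a known `a*` is optimal
(anti-extremise calibrated probabilities with `1/a*`; the transform composes
in log-odds space), the selected values concentrate at `a*`. The grid argmax
at `K = 500` has sampling sd ≈ 0.2, so the recovery test asserts the median
over 30 replicate studies (Monte-Carlo se ≈ 0.05) rather than a single
study's value.

## The crowd simulator

Generative model per event: a latent binary state; a common prior `p₀`
shared by all forecasters (possibly biased — the model allows the prior to
differ from the realized base rate); each forecaster draws one private
signal, conditionally independent given the state, from one of two finite
signal systems. Experts draw from the more informative system; novices from
a garbling of it (`novice likelihoods = expert likelihoods × row-stochastic
confusion matrix`), which guarantees Blackwell dominance by construction.
Reports are exact Bayesian posteriors; meta-predictions are
model-consistent: with `q` the forecaster's posterior and `Ā_T, Ā_F` the
expected report of a random other crowd member in each state,
`M = q·Ā_T + (1 − q)·Ā_F`. Signal spaces are small and finite, so every
population expectation is computed by exact enumeration — the theory tests
(martingale `E[posterior] = prior`; the within-event identity
`|P − M| = (1 − (Ā_T − Ā_F))·|posterior − prior|`, which makes MPW weights
proportional to prior-to-posterior distance; the Blackwell ordering of
expected gaps) hold to machine precision, not Monte-Carlo tolerance.

Default study conditions (five difficulty tiers, each its own crowd and 100
questions, half true): expert signal accuracy 0.90/0.83/0.76/0.69/0.62,
expert fraction 0.85/0.65/0.45/0.30/0.20, novice confusion 0.15–0.45,
prior 0.5, 92 forecasters per tier. The 92 mirrors a 459-person panel each
answering 20 questions per tier spread over 100 questions; the tier mapping
(harder = weaker signals, fewer experts) is this package's convention for
emulating difficulty, which in the original survey was manipulated through
question content. Meta-prediction noise (truncated Gaussian, sd
configurable) is off by default: the theory identities require it off;
realism experiments can turn it on. Votes are derived as `prob ≥ 0.5` (ties
vote true).

### What the simulator does and does not show

Passing the simulator-based tests demonstrates that the implementation
realizes the theory exactly and that MPW's advantage appears where the
theory says it should: in crowds mixing informative experts with weak
novices, extremised MPW beats the extremised simple average in essentially
every replicate, while in homogeneous expert crowds (equal gaps) MPW reduces
to the simple average identically. It does *not* reproduce the full pattern
observed with human forecasters: because simulated forecasters are perfectly
calibrated Bayesians with noiseless, model-consistent meta-predictions,
minimal pivoting — whose correction is nearly exact in this world — and
LOO-recalibrated comparators can outscore extremised MPW on the default
simulated study. With human data, meta-predictions are noisy and
heterogeneous, which is precisely the regime where the published study found
MPW dominant. Behavioural noise models for reports are deliberately out of
scope.

## Exclusion filters

Mirroring the original protocol: (1) all records of forecasters who
self-reported cheating are dropped; (2) records whose vote contradicts the
probability forecast (vote true with `p < 0.5`, vote false with `p > 0.5`;
strict inequalities, so `p = 0.5` is consistent with either vote) are
dropped per (forecaster, event) pair, leaving the forecaster's other
answers intact. The filters are idempotent and commute; both facts are
property-tested. Records missing a meta-prediction are dropped only for
meta-using aggregators (MPW, pivoting) and retained for the simple average.

## Problem sizes and numerical choices

The default test-and-acceptance problem sizes: simulated study 5 × 100
events × 92 forecasters; directional check 50 replicates of 200 events × 50
forecasters; coverage study 1 000 replicates of n = 100 with 1 999 bootstrap
resamples each (above the ≥ 1 000 floor the interval requires, and
sufficient for ±1-point coverage resolution); recalibration grid 1 001
points × 500 folds, evaluated as one K × G score matrix. Probabilities are
stored on the unit scale internally; on-disk scale (percent or unit) is
declared by the reader dialect, eliminating silent 100× errors. Weight
computation is permutation-invariant by algebra; tests assert it.

## Known limitations

* The partial-information `pcs″` aggregator and the vote-based surprisingly
  popular algorithm are intentionally not implemented; comparisons cover the
  simple average, minimal pivoting and the individual benchmark.
* The reproduction tests against the original study's published score
  differences require that study's response data, which is not
  redistributed with the package (see README).
* The simulator commits only to the structural assumptions of the theory
  (common prior, conditional independence, Blackwell-ranked finite signal
  systems, common knowledge of likelihoods); it does not estimate signal
  structures from data.
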