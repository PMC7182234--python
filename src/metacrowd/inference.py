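"""Bias-corrected and accelerated (BCa) bootstrap for paired score differences.

The statistic is the mean per-event difference in transformed Brier score
between two methods; the resampling unit is the event. The BCa interval
adjusts the percentile interval by

* a bias-correction term z0 = Phi^-1 of the fraction of bootstrap means
  below the observed mean (ties counted half), and
* an acceleration term a_hat from the skewness of the jackknife
  (leave-one-event-out) means:

      a_hat = sum(u^3) / (6 * (sum(u^2))^{3/2}),  u_i = mean(jack) - jack_i.

The interval endpoints are the bootstrap quantiles at

      alpha_j = Phi( z0 + (z0 + z_j) / (1 - a_hat * (z0 + z_j)) ).

With z0 = 0 and a_hat = 0 this reduces to the ordinary percentile interval.
A difference is called significant when the interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .aggregation import DEFAULT_A, aggregate_dataset
from .data import Dataset
from .errors import ValidationError
from .scoring import (
    ScoreReport,
    mean_individual_score,
    paired_differences,
    score_aggregates,
)

METHOD_LABELS = (
    "individual_std", "individual_ext",
    "simple_std", "simple_ext",
    "mpw_std", "mpw_ext",
    "pivot_std", "pivot_ext",
)

DEFAULT_N_BOOT = 10_000


@dataclass(frozen=True)
class BootstrapResult:
    """A BCa interval for one paired method comparison in one stratum."""

    method_pair: tuple[str, str]
    stratum: str  # "overall" or "difficulty_<t>"
    mean_difference: float
    ci_low: float
    ci_high: float
    n_events: int
    n_boot: int
    level: float
    seed: int
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0


def bca_interval(diffs, n_boot: int = DEFAULT_N_BOOT, level: float = 0.95,
                 seed: int = 0, method_pair=("a", "b"),
                 stratum: str = "overall") -> BootstrapResult:
    """BCa confidence interval for the mean of ``diffs``.

    Deterministic given (seed, n_boot). An all-identical vector yields the
    degenerate interval [d, d] with a warning.
    """
    x = np.asarray(diffs, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("need at least two paired differences")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    n = len(x)
    obs = float(x.mean())

    if np.ptp(x) == 0.0:
        warnings.warn("all paired differences identical; degenerate interval")
        return BootstrapResult(
            method_pair=tuple(method_pair), stratum=stratum,
            mean_difference=obs, ci_low=obs, ci_high=obs,
            n_events=n, n_boot=n_boot, level=level, seed=seed, degenerate=True,
        )

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = x[idx].mean(axis=1)

    less = np.count_nonzero(boot < obs)
    equal = np.count_nonzero(boot == obs)
    p0 = (less + 0.5 * equal) / n_boot
    # guard against a bootstrap distribution entirely on one side
    p0 = min(max(p0, 0.5 / n_boot), 1.0 - 0.5 / n_boot)
    z0 = norm.ppf(p0)

    jack = (x.sum() - x) / (n - 1)  # leave-one-out means
    u = jack.mean() - jack
    denom = (u ** 2).sum() ** 1.5
    a_hat = 0.0 if denom == 0.0 else float((u ** 3).sum() / (6.0 * denom))

    alpha = 1.0 - level
    z_lo, z_hi = norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)
    a1 = norm.cdf(z0 + (z0 + z_lo) / (1.0 - a_hat * (z0 + z_lo)))
    a2 = norm.cdf(z0 + (z0 + z_hi) / (1.0 - a_hat * (z0 + z_hi)))
    lo, hi = np.quantile(boot, [a1, a2], method="linear")

    if not lo <= obs <= hi:
        warnings.warn(
            f"BCa interval [{lo:.4g}, {hi:.4g}] does not contain the observed "
            f"mean {obs:.4g}; heavy skew in the differences"
        )
    return BootstrapResult(
        method_pair=tuple(method_pair), stratum=stratum,
        mean_difference=obs, ci_low=float(lo), ci_high=float(hi),
        n_events=n, n_boot=n_boot, level=level, seed=seed,
    )


def method_score_report(d: Dataset, label: str, a: float = DEFAULT_A) -> ScoreReport:
    """Score one method (by canonical label) on a filtered dataset."""
    if label not in METHOD_LABELS:
        raise ValidationError(
            f"unknown method label {label!r}; expected one of {METHOD_LABELS}"
        )
    base, variant = label.rsplit("_", 1)
    extremised = variant == "ext"
    if base == "individual":
        return mean_individual_score(d, extremised=extremised, a=a)
    forecasts = aggregate_dataset(d, base, a=a if extremised else None)
    return score_aggregates(forecasts, d, method=label)


def compare_methods(d: Dataset, pairs, a: float = DEFAULT_A,
                    n_boot: int = DEFAULT_N_BOOT, level: float = 0.95,
                    seed: int = 0, per_difficulty: bool = True):
    """Paired BCa comparisons for each (method_a, method_b) label pair.

    Returns one overall :class:`BootstrapResult` per pair, plus one per
    difficulty tier when requested (each tier's question set treated as its
    own dataset). Events scored by one method but not the other are dropped
    from that pair (complete-pairs analysis).
    """
    reports = {}
    for pair in pairs:
        for label in pair:
            if label not in reports:
                reports[label] = method_score_report(d, label, a=a)
    difficulties = d.difficulties()
    results = []
    for label_a, label_b in pairs:
        ra, rb = reports[label_a], reports[label_b]
        common = sorted(set(ra.per_event_scores) & set(rb.per_event_scores))
        if len(common) < len(ra.per_event_scores) or \
           len(common) < len(rb.per_event_scores):
            warnings.warn(
                f"{label_a} vs {label_b}: restricting to {len(common)} "
                "events scored by both methods"
            )
        sub_a = ScoreReport(label_a, {e: ra.per_event_scores[e] for e in common})
        sub_b = ScoreReport(label_b, {e: rb.per_event_scores[e] for e in common})
        _, diffs = paired_differences(sub_a, sub_b)
        results.append(
            bca_interval(diffs, n_boot=n_boot, level=level, seed=seed,
                         method_pair=(label_a, label_b), stratum="overall")
        )
        if per_difficulty:
            tiers = {}
            for ev, delta in zip(common, diffs):
                tiers.setdefault(int(difficulties[ev]), []).append(delta)
            for tier, tier_diffs in sorted(tiers.items()):
                if len(tier_diffs) < 2:
                    warnings.warn(
                        f"difficulty tier {tier}: fewer than two paired "
                        "events; stratum skipped"
                    )
                    continue
                results.append(
                    bca_interval(
                        tier_diffs, n_boot=n_boot, level=level, seed=seed,
                        method_pair=(label_a, label_b),
                        stratum=f"difficulty_{tier}",
                    )
                )
    return results
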