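"""Bayesian common-prior / private-signal crowd simulator.

Generative model for one event:

* A latent binary state (the statement is true or false). All forecasters
  share a common prior p0 for "true"; the prior may be biased away from the
  realized base rate.
* Each forecaster receives one private signal from one of two finite
  information systems — *experts* draw from the more informative system,
  *novices* from a garbling of it, so the expert system Blackwell-dominates
  the novice system by construction. Signals are independent conditional on
  the state.
* Forecasters report their exact Bayesian posterior as their probability
  forecast, and a model-consistent meta-prediction of the average report of
  others: with q their own posterior and A_T, A_F the expected report of a
  random other forecaster in the true/false state,

      meta = q * A_T + (1 - q) * A_F.

Signal likelihoods are common knowledge, so two forecasters with the same
signal make the same meta-prediction. All population expectations (A_T, A_F,
expected posterior gaps) are computed by exact enumeration over the finite
signal space — no Monte Carlo — which makes the theory's identities testable
to machine precision:

* martingale: E[posterior] = prior over the signal marginal;
* within an event, |P - M| = (1 - (A_T - A_F)) * |posterior - prior|, so
  MPW weights are proportional to the prior-to-posterior distance;
* garbling shrinks E|posterior - prior|, hence expected expert weight >=
  expected novice weight (Blackwell ordering).

Difficulty tiers are emulated by weakening the signal systems and lowering
the expert fraction tier by tier — an artifact convention standing in for
harder question content.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import Dataset
from .errors import ValidationError


@dataclass(frozen=True)
class SignalSystem:
    """A finite information system: P(signal | state) in each state."""

    labels: tuple
    likelihood_true: np.ndarray
    likelihood_false: np.ndarray

    def __post_init__(self):
        lt = np.asarray(self.likelihood_true, dtype=float)
        lf = np.asarray(self.likelihood_false, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "likelihood_true", lt)
        object.__setattr__(self, "likelihood_false", lf)
        if len(self.labels) != len(lt) or len(self.labels) != len(lf):
            raise ValidationError("labels and likelihood vectors disagree in length")
        for name, v in (("likelihood_true", lt), ("likelihood_false", lf)):
            if (v < 0).any():
                raise ValidationError(f"{name} has negative entries")
            if abs(v.sum() - 1.0) > 1e-12:
                raise ValidationError(f"{name} sums to {v.sum()!r}, expected 1")

    def index(self, signal) -> int:
        try:
            return self.labels.index(signal)
        except ValueError:
            raise ValidationError(f"unknown signal {signal!r}")

    def marginal(self, prior: float) -> np.ndarray:
        """P(signal) under the prior."""
        return prior * self.likelihood_true + (1.0 - prior) * self.likelihood_false

    def posteriors(self, prior: float) -> np.ndarray:
        """Bayes posterior P(true | signal) for every signal."""
        num = prior * self.likelihood_true
        den = num + (1.0 - prior) * self.likelihood_false
        if (den == 0).any():
            raise ValidationError(
                "some signal has zero probability under both states"
            )
        return num / den

    def expected_posterior_gap(self, prior: float) -> float:
        """E|posterior - prior| over the signal marginal — the enumeration
        quantity behind the Blackwell weight ordering."""
        return float(np.dot(self.marginal(prior),
                            np.abs(self.posteriors(prior) - prior)))


def binary_symmetric(accuracy: float, labels=("hi", "lo")) -> SignalSystem:
    """Two-signal system where the state-matching signal arrives with the
    given accuracy in either state."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValidationError("accuracy must be in [0, 1]")
    return SignalSystem(
        labels=labels,
        likelihood_true=np.array([accuracy, 1.0 - accuracy]),
        likelihood_false=np.array([1.0 - accuracy, accuracy]),
    )


def posterior(prior: float, system: SignalSystem, signal) -> float:
    """P(true | signal) = p0 P(s|T) / (p0 P(s|T) + (1-p0) P(s|F))."""
    if not 0.0 < prior < 1.0:
        raise ValidationError("prior must be in the open interval (0, 1)")
    i = system.index(signal)
    num = prior * system.likelihood_true[i]
    den = num + (1.0 - prior) * system.likelihood_false[i]
    if den == 0.0:
        raise ValidationError(
            f"signal {signal!r} has zero probability under both states"
        )
    return float(num / den)


def make_garbled(expert: SignalSystem, confusion) -> SignalSystem:
    """Novice system whose signal is a stochastic degradation of the expert's.

    ``confusion[i, j]`` = P(novice observes label j | expert label i); rows
    must sum to one. The result is Blackwell-dominated by the expert system.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != len(expert.labels):
        raise ValidationError("confusion matrix shape does not match signal space")
    if (c < 0).any() or not np.allclose(c.sum(axis=1), 1.0, atol=1e-12):
        raise ValidationError("confusion matrix must be row-stochastic")
    labels = tuple(f"g{j}" for j in range(c.shape[1])) \
        if c.shape[1] != len(expert.labels) else expert.labels
    return SignalSystem(
        labels=labels,
        likelihood_true=expert.likelihood_true @ c,
        likelihood_false=expert.likelihood_false @ c,
    )


def expected_report(prior: float, population) -> tuple[float, float]:
    """(A_T, A_F): expected posterior report of a random forecaster in each
    state, for a population given as [(SignalSystem, weight), ...]."""
    weights = np.array([w for _, w in population], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValidationError("population mixture weights must sum to 1")
    a_t = a_f = 0.0
    for system, w in population:
        q = system.posteriors(prior)
        a_t += w * float(np.dot(system.likelihood_true, q))
        a_f += w * float(np.dot(system.likelihood_false, q))
    return a_t, a_f


def meta_prediction(prior: float, own_system: SignalSystem, own_signal,
                    population) -> float:
    """Model-consistent prediction of the average report of others:
    q * A_T + (1 - q) * A_F with q the forecaster's own posterior."""
    q = posterior(prior, own_system, own_signal)
    a_t, a_f = expected_report(prior, population)
    return q * a_t + (1.0 - q) * a_f


def expected_vote_share(prior: float, population) -> tuple[float, float]:
    """(V_T, V_F): probability a random forecaster votes true in each state
    (vote = posterior > 0.5, ties voting true)."""
    v_t = v_f = 0.0
    for system, w in population:
        votes = (system.posteriors(prior) >= 0.5).astype(float)
        v_t += w * float(np.dot(system.likelihood_true, votes))
        v_f += w * float(np.dot(system.likelihood_false, votes))
    return v_t, v_f


@dataclass(frozen=True)
class CrowdConfig:
    """Study conditions for one difficulty tier."""

    n_forecasters: int
    expert_fraction: float
    prior: float
    expert_system: SignalSystem
    novice_system: SignalSystem
    meta_noise_sd: float = 0.0

    def __post_init__(self):
        if self.n_forecasters < 1:
            raise ValidationError("n_forecasters must be >= 1")
        if not 0.0 <= self.expert_fraction <= 1.0:
            raise ValidationError("expert_fraction must be in [0, 1]")
        if not 0.0 < self.prior < 1.0:
            raise ValidationError("prior must be in (0, 1)")
        if self.meta_noise_sd < 0:
            raise ValidationError("meta_noise_sd must be nonnegative")

    @property
    def population(self):
        return [
            (self.expert_system, self.expert_fraction),
            (self.novice_system, 1.0 - self.expert_fraction),
        ]


@dataclass
class SimulatedStudy:
    """A simulated dataset plus the latent ground truth behind it."""

    dataset: Dataset
    truth_table: pd.DataFrame  # per (forecaster, event): type, signal, state
    configs: dict = field(default_factory=dict)


# Tier defaults: harder tiers get weaker signals and fewer experts. 92
# forecasters per tier mirrors a 459-person panel answering 20 questions per
# tier spread over 100 questions.
_TIER_EXPERT_ACC = {1: 0.90, 2: 0.83, 3: 0.76, 4: 0.69, 5: 0.62}
_TIER_EXPERT_FRAC = {1: 0.85, 2: 0.65, 3: 0.45, 4: 0.30, 5: 0.20}
_TIER_GARBLE = {1: 0.15, 2: 0.25, 3: 0.33, 4: 0.40, 5: 0.45}


def default_tier_configs(n_forecasters: int = 92, prior: float = 0.5,
                         meta_noise_sd: float = 0.0) -> dict[int, CrowdConfig]:
    """The default study conditions: five difficulty tiers, informativeness
    and expert share declining with difficulty."""
    configs = {}
    for tier in range(1, 6):
        expert = binary_symmetric(_TIER_EXPERT_ACC[tier])
        eps = _TIER_GARBLE[tier]
        novice = make_garbled(expert, [[1 - eps, eps], [eps, 1 - eps]])
        configs[tier] = CrowdConfig(
            n_forecasters=n_forecasters,
            expert_fraction=_TIER_EXPERT_FRAC[tier],
            prior=prior,
            expert_system=expert,
            novice_system=novice,
            meta_noise_sd=meta_noise_sd,
        )
    return configs


def simulate_study(configs, events_per_tier: int = 100,
                   seed: int = 0) -> SimulatedStudy:
    """Simulate a full study: per tier, a fresh crowd answers every event.

    Exactly half the events in each tier are true (positions shuffled).
    Forecaster type (expert/novice) is drawn once per forecaster and held
    fixed across the tier's events. Reports are exact posteriors;
    meta-predictions get optional truncated Gaussian noise (sd =
    ``meta_noise_sd``, clamped to [0, 1]). Votes are prob > 0.5 with ties
    voting true. Deterministic given ``seed``.
    """
    if events_per_tier < 2 or events_per_tier % 2 != 0:
        raise ValidationError("events_per_tier must be a positive even number")
    configs = dict(configs)
    rng = np.random.default_rng(seed)

    rec_rows, ev_rows, truth_rows = [], [], []
    for tier in sorted(configs):
        cfg = configs[tier]
        states = np.array([1] * (events_per_tier // 2)
                          + [0] * (events_per_tier // 2))
        rng.shuffle(states)
        event_ids = [f"T{tier}E{j:04d}" for j in range(events_per_tier)]
        for ev, st in zip(event_ids, states):
            ev_rows.append({"event_id": ev, "truth": int(st), "difficulty": tier,
                            "statement": ""})

        is_expert = rng.random(cfg.n_forecasters) < cfg.expert_fraction
        forecaster_ids = [f"T{tier}F{i:04d}" for i in range(cfg.n_forecasters)]

        pop = cfg.population
        a_t, a_f = expected_report(cfg.prior, pop)
        v_t, v_f = expected_vote_share(cfg.prior, pop)
        systems = {True: cfg.expert_system, False: cfg.novice_system}
        post = {k: s.posteriors(cfg.prior) for k, s in systems.items()}

        # draw all signals at once: invert the per-(type, state) signal CDF
        E, N = events_per_tier, cfg.n_forecasters
        u = rng.random((E, N))
        sig_idx = np.empty((E, N), dtype=int)
        qmat = np.empty((E, N))
        for exp_flag in (True, False):
            sys_ = systems[exp_flag]
            cols = np.flatnonzero(is_expert == exp_flag)
            if cols.size == 0:
                continue
            for state_val, lik in ((1, sys_.likelihood_true),
                                   (0, sys_.likelihood_false)):
                rows = np.flatnonzero(states == state_val)
                cum = np.cumsum(lik)
                idx = np.searchsorted(cum, u[np.ix_(rows, cols)], side="right")
                sig_idx[np.ix_(rows, cols)] = idx
                qmat[np.ix_(rows, cols)] = post[exp_flag][idx]
        meta = qmat * a_t + (1.0 - qmat) * a_f
        if cfg.meta_noise_sd > 0:
            meta = np.clip(meta + rng.normal(0.0, cfg.meta_noise_sd, (E, N)),
                           0.0, 1.0)
        share = qmat * v_t + (1.0 - qmat) * v_f

        ev_rep = np.repeat(event_ids, N)
        fid_tile = np.tile(forecaster_ids, E)
        rec_rows.append(pd.DataFrame({
            "forecaster_id": fid_tile,
            "event_id": ev_rep,
            "vote": (qmat >= 0.5).ravel(),  # ties vote true
            "meta_vote_share": share.ravel(),
            "prob": qmat.ravel(),
            "meta_prob": meta.ravel(),
            "cheater": False,
        }))
        signal_names = np.empty((E, N), dtype=object)
        for exp_flag in (True, False):
            cols = np.flatnonzero(is_expert == exp_flag)
            if cols.size == 0:
                continue
            lab = np.array(systems[exp_flag].labels, dtype=object)
            signal_names[:, cols] = lab[sig_idx[:, cols]]
        truth_rows.append(pd.DataFrame({
            "forecaster_id": fid_tile,
            "event_id": ev_rep,
            "difficulty": tier,
            "is_expert": np.tile(is_expert, E),
            "signal": signal_names.ravel(),
            "state": np.repeat(states, N),
            "posterior": qmat.ravel(),
            "prior": cfg.prior,
        }))

    dataset = Dataset(
        records=pd.concat(rec_rows, ignore_index=True),
        events=pd.DataFrame(ev_rows),
        provenance=[f"simulated study: seed={seed}, "
                    f"{events_per_tier} events/tier, tiers={sorted(configs)}"],
    )
    return SimulatedStudy(dataset=dataset,
                          truth_table=pd.concat(truth_rows, ignore_index=True),
                          configs=configs)


def mixed_crowd_config(n_forecasters: int = 50, expert_fraction: float = 0.3,
                       expert_accuracy: float = 0.85, garble: float = 0.45,
                       prior: float = 0.5,
                       meta_noise_sd: float = 0.0) -> CrowdConfig:
    """A heterogeneous crowd — informative experts in a sea of weak novices —
    the regime where weighting by meta-prediction gaps should pay off."""
    expert = binary_symmetric(expert_accuracy)
    novice = make_garbled(expert, [[1 - garble, garble], [garble, 1 - garble]])
    return CrowdConfig(n_forecasters=n_forecasters,
                       expert_fraction=expert_fraction, prior=prior,
                       expert_system=expert, novice_system=novice,
                       meta_noise_sd=meta_noise_sd)


def homogeneous_expert_config(n_forecasters: int = 50,
                              expert_accuracy: float = 0.85,
                              prior: float = 0.5) -> CrowdConfig:
    """An all-expert crowd: every forecaster equally informed, the regime
    where weighting offers nothing over the simple average."""
    expert = binary_symmetric(expert_accuracy)
    return CrowdConfig(n_forecasters=n_forecasters, expert_fraction=1.0,
                       prior=prior, expert_system=expert,
                       novice_system=replace(expert))
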