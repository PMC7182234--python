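"""The Bayesian common-prior / private-signal crowd simulator and the
information-theoretic properties behind meta-prediction weighting."""

import numpy as np
import pandas as pd
import pytest

from metacrowd.aggregation import mpw_weights
from metacrowd.errors import ValidationError
from metacrowd.simulator import (
    SignalSystem,
    binary_symmetric,
    default_tier_configs,
    expected_report,
    homogeneous_expert_config,
    make_garbled,
    meta_prediction,
    mixed_crowd_config,
    posterior,
    simulate_study,
)


@pytest.fixture
def expert():
    return binary_symmetric(0.9)


class TestPosterior:
    def test_uninformative_signal_returns_prior(self):
        flat = SignalSystem(("a", "b"), [0.5, 0.5], [0.5, 0.5])
        assert posterior(0.37, flat, "a") == pytest.approx(0.37)

    def test_even_prior_arithmetic(self):
        sys_ = SignalSystem(("s", "t"), [0.7, 0.3], [0.3, 0.7])
        assert posterior(0.5, sys_, "s") == pytest.approx(0.7)

    def test_biased_prior_bayes(self):
        sys_ = SignalSystem(("s", "t"), [0.6, 0.4], [0.9, 0.1])
        assert posterior(0.8, sys_, "s") == pytest.approx(8 / 11)

    def test_unknown_signal_rejected(self, expert):
        with pytest.raises(ValidationError):
            posterior(0.5, expert, "nope")

    def test_martingale_by_enumeration(self, expert):
        for prior in (0.2, 0.5, 0.73):
            q = expert.posteriors(prior)
            assert np.dot(expert.marginal(prior), q) == \
                pytest.approx(prior, abs=1e-12)


class TestMakeGarbled:
    def test_identity_confusion_preserves_system(self, expert):
        novice = make_garbled(expert, np.eye(2))
        np.testing.assert_allclose(novice.likelihood_true,
                                   expert.likelihood_true)

    def test_uniform_confusion_destroys_information(self, expert):
        novice = make_garbled(expert, np.full((2, 2), 0.5))
        np.testing.assert_allclose(novice.posteriors(0.4), [0.4, 0.4])

    def test_known_matrix_product(self, expert):
        novice = make_garbled(expert, [[0.8, 0.2], [0.2, 0.8]])
        np.testing.assert_allclose(novice.likelihood_true, [0.74, 0.26])
        np.testing.assert_allclose(novice.likelihood_false, [0.26, 0.74])

    def test_non_stochastic_matrix_rejected(self, expert):
        with pytest.raises(ValidationError):
            make_garbled(expert, [[0.9, 0.2], [0.2, 0.8]])

    @pytest.mark.parametrize("prior", [0.3, 0.5, 0.8])
    def test_blackwell_ordering_of_posterior_gaps(self, expert, prior):
        # any garbling weakly shrinks E|posterior - prior|; a strictly
        # information-losing garbling shrinks it strictly
        for eps in (0.1, 0.25, 0.4):
            novice = make_garbled(expert, [[1 - eps, eps], [eps, 1 - eps]])
            assert novice.expected_posterior_gap(prior) < \
                expert.expected_posterior_gap(prior)
        same = make_garbled(expert, np.eye(2))
        assert same.expected_posterior_gap(prior) == \
            pytest.approx(expert.expected_posterior_gap(prior))


class TestMetaPrediction:
    def test_uninformative_own_signal_gives_prior(self, expert):
        # law of total expectation: q = prior implies
        # meta = p0*A_T + (1-p0)*A_F = E[posterior] = prior
        flat = SignalSystem(("a", "b"), [0.5, 0.5], [0.5, 0.5])
        pop = [(expert, 0.4), (flat, 0.6)]
        for prior in (0.25, 0.5, 0.66):
            assert meta_prediction(prior, flat, "a", pop) == \
                pytest.approx(prior, abs=1e-12)

    def test_certain_posterior_gives_state_conditional_mean(self):
        revealing = SignalSystem(("t", "f"), [1.0, 0.0], [0.0, 1.0])
        pop = [(revealing, 0.5), (binary_symmetric(0.7), 0.5)]
        a_t, _ = expected_report(0.5, pop)
        assert meta_prediction(0.5, revealing, "t", pop) == \
            pytest.approx(a_t, abs=1e-12)

    def test_brute_force_enumeration_oracle(self):
        # symmetric binary system, prior 0.5, accuracy 0.8: enumerate A_T,
        # A_F and the per-signal meta-predictions by explicit summation
        sys_ = binary_symmetric(0.8)
        pop = [(sys_, 1.0)]
        q = {s: posterior(0.5, sys_, s) for s in sys_.labels}
        a_t = sum(lik * q[s] for s, lik in
                  zip(sys_.labels, sys_.likelihood_true))
        a_f = sum(lik * q[s] for s, lik in
                  zip(sys_.labels, sys_.likelihood_false))
        assert a_t == pytest.approx(0.8 * 0.8 + 0.2 * 0.2)
        assert a_f == pytest.approx(0.2 * 0.8 + 0.8 * 0.2)
        for s in sys_.labels:
            expected = q[s] * a_t + (1 - q[s]) * a_f
            assert meta_prediction(0.5, sys_, s, pop) == \
                pytest.approx(expected, abs=1e-12)

    def test_same_signal_same_meta_prediction(self, expert):
        pop = [(expert, 1.0)]
        m1 = meta_prediction(0.5, expert, "hi", pop)
        m2 = meta_prediction(0.5, expert, "hi", pop)
        assert m1 == m2


class TestSimulateStudy:
    def test_half_events_true_per_tier(self):
        study = simulate_study(default_tier_configs(n_forecasters=10),
                               events_per_tier=20, seed=0)
        ev = study.dataset.events
        for tier, grp in ev.groupby("difficulty"):
            assert grp["truth"].sum() == 10

    def test_same_seed_reproduces_exactly(self):
        cfgs = default_tier_configs(n_forecasters=8)
        a = simulate_study(cfgs, events_per_tier=10, seed=5)
        b = simulate_study(cfgs, events_per_tier=10, seed=5)
        pd.testing.assert_frame_equal(a.dataset.records, b.dataset.records)
        pd.testing.assert_frame_equal(a.dataset.events, b.dataset.events)

    def test_forecaster_type_constant_within_tier(self):
        study = simulate_study({1: mixed_crowd_config(n_forecasters=12)},
                               events_per_tier=10, seed=2)
        types = study.truth_table.groupby("forecaster_id")["is_expert"].nunique()
        assert (types == 1).all()

    def test_probabilities_in_unit_interval_with_meta_noise(self):
        cfg = mixed_crowd_config(n_forecasters=15, meta_noise_sd=0.3)
        study = simulate_study({1: cfg}, events_per_tier=10, seed=3)
        r = study.dataset.records
        assert r["prob"].between(0, 1).all()
        assert r["meta_prob"].between(0, 1).all()
        assert r["meta_vote_share"].between(0, 1).all()

    def test_votes_follow_posteriors(self):
        study = simulate_study({1: mixed_crowd_config(n_forecasters=10)},
                               events_per_tier=10, seed=4)
        r = study.dataset.records
        assert (r["vote"] == (r["prob"] >= 0.5)).all()

    def test_weight_posterior_identity_noiseless(self):
        # with noiseless meta-predictions, |P - M| = c * |posterior - prior|
        # within an event, c = 1 - (A_T - A_F); hence MPW weights are
        # proportional to the prior-to-posterior distance
        cfg = mixed_crowd_config(n_forecasters=25)
        study = simulate_study({1: cfg}, events_per_tier=6, seed=6)
        a_t, a_f = expected_report(cfg.prior, cfg.population)
        c = 1.0 - (a_t - a_f)
        r = study.dataset.records
        gaps = np.abs(r["prob"] - r["meta_prob"])
        np.testing.assert_allclose(
            gaps, c * np.abs(r["prob"] - cfg.prior), atol=1e-12)
        for _, grp in r.groupby("event_id"):
            w = mpw_weights(grp["prob"].to_numpy(), grp["meta_prob"].to_numpy())
            dist = np.abs(grp["prob"].to_numpy() - cfg.prior)
            if dist.sum() > 0:
                np.testing.assert_allclose(w.weights, dist / dist.sum(),
                                           atol=1e-12)

    def test_expert_expected_weight_exceeds_novice(self):
        # Blackwell ordering surfaces in realized MPW weights
        cfg = mixed_crowd_config(n_forecasters=60, expert_fraction=0.5)
        study = simulate_study({1: cfg}, events_per_tier=40, seed=7)
        merged = study.dataset.records.merge(
            study.truth_table[["forecaster_id", "event_id", "is_expert"]],
            on=["forecaster_id", "event_id"])
        weights = []
        for _, grp in merged.groupby("event_id"):
            w = mpw_weights(grp["prob"].to_numpy(), grp["meta_prob"].to_numpy())
            weights.append(pd.DataFrame(
                {"w": w.weights, "is_expert": grp["is_expert"].to_numpy()}))
        wdf = pd.concat(weights)
        assert wdf.loc[wdf["is_expert"], "w"].mean() > \
            wdf.loc[~wdf["is_expert"], "w"].mean()

    def test_homogeneous_crowd_types_indistinguishable(self):
        cfg = homogeneous_expert_config(n_forecasters=20)
        study = simulate_study({1: cfg}, events_per_tier=10, seed=8)
        r = study.dataset.records
        # everyone shares one system: the set of distinct reported
        # probabilities per event is at most the signal count
        assert r.groupby("event_id")["prob"].nunique().le(2).all()

    def test_odd_events_per_tier_rejected(self):
        with pytest.raises(ValidationError):
            simulate_study({1: mixed_crowd_config()}, events_per_tier=7, seed=0)


class TestCrowdConfigValidation:
    def test_prior_must_be_interior(self):
        with pytest.raises(ValidationError):
            mixed_crowd_config(prior=1.0)

    def test_expert_fraction_bounds(self):
        with pytest.raises(ValidationError):
            mixed_crowd_config(expert_fraction=1.2)

    def test_likelihoods_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            SignalSystem(("a", "b"), [0.6, 0.6], [0.5, 0.5])
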