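"""Tests of the Psi adaptive procedure: init, placement, update, readout."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit

from gazeprior import (
    GazeObserver,
    PsychometricModel,
    default_model,
    psi_init,
    psi_next_level,
    psi_threshold,
    psi_update,
    run_calibration,
)


def toy_model(criterion=0.803):
    return PsychometricModel(
        alpha_grid=np.log([0.1, 0.2, 0.4]),
        beta_grid=np.array([1.0, 4.0]),
        levels=np.array([0.08, 0.2, 0.5]),
        criterion=criterion,
    )


def family_prob(level, alpha, beta, model):
    span = 1.0 - model.guess_rate - model.lapse_rate
    shift = logit((model.criterion - model.guess_rate) / span)
    return model.guess_rate + span * expit(-beta * (np.log(level) - alpha) + shift)


class TestInit:
    def test_uniform_posterior_by_default(self):
        state = psi_init(toy_model())
        assert state.posterior.shape == (3, 2)
        assert np.allclose(state.posterior, 1.0 / 6.0)
        assert state.trial_count == 0

    def test_supplied_prior_is_normalised_and_kept(self):
        prior = np.zeros((3, 2))
        prior[1, 0] = 5.0
        state = psi_init(toy_model(), prior)
        assert state.posterior[1, 0] == 1.0
        assert state.posterior.sum() == pytest.approx(1.0)

    def test_degenerate_single_cell_grid(self):
        model = PsychometricModel(
            alpha_grid=np.log([0.2]), beta_grid=np.array([2.0]),
            levels=np.array([0.1, 0.3]),
        )
        assert psi_init(model).posterior[0, 0] == 1.0

    def test_non_normalisable_prior_rejected(self):
        with pytest.raises(ValueError):
            psi_init(toy_model(), np.zeros((3, 2)))


class TestNextLevel:
    def test_matches_exhaustive_entropy_enumeration(self):
        # independent brute-force oracle over all (level, response) outcomes
        model = toy_model()
        rng = np.random.default_rng(7)
        prior = rng.random((3, 2))
        state = psi_init(model, prior)
        post = state.posterior.ravel()
        cells = [(a, b) for a in model.alpha_grid for b in model.beta_grid]
        best_level, best_eh = None, math.inf
        for level in model.levels:
            probs = np.array([family_prob(level, a, b, model) for a, b in cells])
            eh = 0.0
            for resp in (True, False):
                lik = probs if resp else 1 - probs
                joint = post * lik
                tot = joint.sum()
                q = joint / tot
                eh += tot * float(-(q * np.log(q)).sum())
            if eh < best_eh - 1e-12:
                best_eh, best_level = eh, level
        assert psi_next_level(state, model) == pytest.approx(best_level)

    def test_deterministic_for_concentrated_posterior(self):
        model = toy_model()
        prior = np.zeros((3, 2))
        prior[2, 1] = 1.0
        state = psi_init(model, prior)
        first = psi_next_level(state, model)
        assert all(psi_next_level(state, model) == first for _ in range(3))


class TestUpdate:
    def test_posterior_mass_conserved_over_a_run(self):
        model = default_model()
        rng = np.random.default_rng(0)
        state = psi_init(model)
        for _ in range(40):
            level = float(rng.choice(model.levels))
            state = psi_update(state, level, bool(rng.integers(2)), model)
            assert state.posterior.sum() == pytest.approx(1.0, abs=1e-12)
            assert (state.posterior >= 0).all()

    def test_two_updates_commute_with_joint_update(self):
        model = toy_model()
        s0 = psi_init(model)
        a = psi_update(psi_update(s0, 0.08, True, model), 0.5, False, model)
        b = psi_update(psi_update(s0, 0.5, False, model), 0.08, True, model)
        assert np.allclose(a.posterior, b.posterior, atol=1e-14)

    def test_hand_computed_two_cell_bayes_update(self):
        # 2 alphas x 1 beta: posterior ratio after a success is psi1/psi2
        model = PsychometricModel(
            alpha_grid=np.log([0.1, 0.4]), beta_grid=np.array([2.0]),
            levels=np.array([0.2]),
        )
        p1 = family_prob(0.2, math.log(0.1), 2.0, model)
        p2 = family_prob(0.2, math.log(0.4), 2.0, model)
        state = psi_update(psi_init(model), 0.2, True, model)
        expected = np.array([[p1], [p2]]) / (p1 + p2)
        assert np.allclose(state.posterior, expected, atol=1e-14)
        assert state.history == ((0.2, 1),)

    def test_uninformative_trial_leaves_posterior_unchanged(self):
        # far below every alpha the family saturates, so all cells agree
        model = PsychometricModel(
            alpha_grid=np.log([0.5, 0.8]), beta_grid=np.array([6.0, 9.0]),
            levels=np.array([1e-4, 0.6]),
        )
        state = psi_update(psi_init(model), 1e-4, True, model)
        assert np.allclose(state.posterior, 0.25, atol=1e-4)

    def test_level_outside_level_set_rejected(self):
        model = toy_model()
        with pytest.raises(ValueError):
            psi_update(psi_init(model), 0.123, True, model)


class TestThresholdReadout:
    def test_concentrated_posterior_inverts_analytically(self):
        model = toy_model()
        prior = np.zeros((3, 2))
        prior[1, 1] = 1.0  # alpha = log 0.2, beta = 4
        state = psi_init(model, prior)
        # at the model's own criterion the threshold is exp(alpha) itself
        assert psi_threshold(state, model, 0.803) == pytest.approx(0.2)
        # at another criterion, invert the logistic by hand
        crit = 0.7
        span = 1.0 - model.guess_rate - model.lapse_rate
        shift = logit((model.criterion - model.guess_rate) / span)
        x = math.log(0.2) + (shift - logit((crit - 0.5) / span)) / 4.0
        assert psi_threshold(state, model, crit) == pytest.approx(math.exp(x))
        # lower criterion -> tolerates more noise -> higher threshold
        assert psi_threshold(state, model, 0.7) > psi_threshold(state, model, 0.9)

    @pytest.mark.parametrize("bad", [0.5, 0.49, 0.99, 1.2])
    def test_unattainable_criterion_rejected(self, bad):
        model = toy_model()
        with pytest.raises(ValueError):
            psi_threshold(psi_init(model), model, bad)


class TestCalibration:
    def test_run_structure_and_median(self, psi_model):
        obs = GazeObserver(20.0, 2.0, 75.0, lapse_rate=0.02)
        res = run_calibration(
            obs, model=psi_model, n_runs=4, n_trials=30,
            rng=np.random.default_rng(3),
        )
        assert len(res.trials) == 120
        assert sorted(res.trials["run"].unique()) == [1, 2, 3, 4]
        assert (res.trials.groupby("run").size() == 30).all()
        assert len(res.run_thresholds) == 4
        assert res.threshold == pytest.approx(float(np.median(res.run_thresholds)))

    def test_single_run_median_is_identity(self, psi_model):
        obs = GazeObserver(20.0, 2.0, 75.0)
        res = run_calibration(
            obs, model=psi_model, n_runs=1, n_trials=15,
            rng=np.random.default_rng(5),
        )
        assert res.threshold == res.run_thresholds[0]

    def test_threshold_independent_of_prior_width(self, psi_model):
        kwargs = dict(clean_sensory_sd_deg=2.0, noise_gain=75.0, lapse_rate=0.02)
        narrow = GazeObserver(prior_sd_deg=8.0, **kwargs)
        flat = GazeObserver(prior_sd_deg=math.inf, **kwargs)
        r1 = run_calibration(narrow, model=psi_model, rng=np.random.default_rng(11))
        r2 = run_calibration(flat, model=psi_model, rng=np.random.default_rng(11))
        assert r1.threshold == r2.threshold
        assert r1.trials.equals(r2.trials)

    def test_mean_posterior_entropy_decreases_over_trials(self, psi_model):
        from gazeprior.observer import StimulusSpec, respond_lr_detection
        from gazeprior.psi import psi_init

        obs = GazeObserver(20.0, 2.0, 75.0, lapse_rate=0.02)
        rng = np.random.default_rng(21)
        entropies = np.zeros((40, 31))
        for rep in range(40):
            state = psi_init(psi_model)
            for t in range(30):
                post = state.posterior.ravel()
                entropies[rep, t] = -(post[post > 0] * np.log(post[post > 0])).sum()
                level = psi_next_level(state, psi_model)
                side = 15.0 if rng.random() < 0.5 else -15.0
                resp = respond_lr_detection(
                    obs, StimulusSpec(side, True, level), rng
                )
                state = psi_update(state, level, resp, psi_model)
            post = state.posterior.ravel()
            entropies[rep, 30] = -(post[post > 0] * np.log(post[post > 0])).sum()
        mean_h = entropies.mean(axis=0)
        assert (np.diff(mean_h) < 0.02).all()  # non-increasing in expectation
        assert mean_h[-1] < mean_h[0] - 1.0

    def test_longer_runs_shrink_threshold_spread(self, psi_model):
        obs = GazeObserver(20.0, 2.0, 75.0, lapse_rate=0.02)
        est = {30: [], 300: []}
        for n_trials in est:
            for i in range(40):
                rng = np.random.default_rng(np.random.SeedSequence([n_trials, i]))
                res = run_calibration(
                    obs, model=psi_model, n_runs=1, n_trials=n_trials, rng=rng
                )
                est[n_trials].append(res.threshold)
        assert np.std(est[300]) < np.std(est[30])
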