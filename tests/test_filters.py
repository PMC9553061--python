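"""Single-template filter: hazard, drift, event reset, full runs."""

import math

import numpy as np
import pytest

from pippet.domain import (ExpectationTemplate, FilterConfig, PhasePosterior,
                           make_two_interval_template)
from pippet.filters import (PippetModel, drift_step, event_update, hazard,
                            run_pippet)
from pippet.rhythm_space import make_stimulus


def _background_template(lam0=0.02):
    # a single zero-strength expectation: rate is background everywhere
    return ExpectationTemplate(event_phases=[0.5], event_variances=[1e-4],
                               event_strengths=[0.0], background_rate=lam0,
                               cycle_period=1.0)


def _random_state(rng, n_events=3):
    phases = np.sort(rng.uniform(0.5, 2.0, n_events))
    template = ExpectationTemplate(
        event_phases=phases,
        event_variances=rng.uniform(1e-4, 5e-3, n_events),
        event_strengths=rng.uniform(0.05, 0.5, n_events),
        background_rate=rng.uniform(1e-3, 0.05),
        cycle_period=2.5)
    posterior = PhasePosterior(mean=rng.uniform(0.5, 2.0),
                               variance=rng.uniform(1e-4, 5e-3))
    return template, posterior


class TestHazard:
    def test_no_events_gives_background(self):
        lam, lam_i = hazard(_background_template(0.02),
                            PhasePosterior(0.3, 1e-3))
        assert lam == pytest.approx(0.02)
        assert lam_i == pytest.approx([0.0])

    def test_peak_scaling_in_small_variance_limit(self):
        # at mu = phi_1 the conditional hazard is lambda_1/sqrt(2pi(v+V))
        for v, V in ((1e-4, 1e-6), (1e-5, 1e-7), (1e-6, 1e-8)):
            t = ExpectationTemplate(event_phases=[0.5],
                                    event_variances=[v],
                                    event_strengths=[0.7],
                                    background_rate=1e-3, cycle_period=1.0)
            _, lam_i = hazard(t, PhasePosterior(0.5, V))
            assert lam_i[0] == pytest.approx(
                0.7 / math.sqrt(2 * math.pi * (v + V)), rel=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(20):
            t, post = _random_state(rng)
            lam, lam_i = hazard(t, post)
            oracle_i = [
                s * math.exp(-0.5 * (post.mean - p) ** 2
                             / (v + post.variance))
                / math.sqrt(2 * math.pi * (v + post.variance))
                for p, v, s in zip(t.event_phases, t.event_variances,
                                   t.event_strengths)]
            assert lam_i == pytest.approx(oracle_i, abs=1e-12)
            assert lam == pytest.approx(t.background_rate + sum(oracle_i),
                                        abs=1e-12)


class TestDriftStep:
    def test_background_only_identity(self, quiet_config):
        # with only background expected, mu advances by exactly dt and V by
        # sigma^2 dt (the reset moments equal the current moments)
        post = PhasePosterior(0.3, 2e-4)
        t = _background_template()
        out = drift_step(post, t, quiet_config, event_occurred=False)
        assert out.mean == pytest.approx(post.mean + quiet_config.dt,
                                         abs=1e-15)
        assert out.variance == pytest.approx(
            post.variance + quiet_config.sigma ** 2 * quiet_config.dt,
            abs=1e-15)

    def test_closed_form_diffusion(self, quiet_config):
        # 1000 steps with no events: V_t = V_0 + sigma^2 t
        post = PhasePosterior(0.0, 2e-4)
        t = _background_template()
        for _ in range(1000):
            post = drift_step(post, t, quiet_config, event_occurred=False)
        expected = 2e-4 + quiet_config.sigma ** 2 * 1000 * quiet_config.dt
        assert post.variance == pytest.approx(expected, abs=1e-10)
        assert post.mean == pytest.approx(1000 * quiet_config.dt, abs=1e-10)


class TestEventUpdate:
    def test_conjugate_gaussian_limit(self):
        # single expectation, negligible background, mu_t = phi_1
        t = ExpectationTemplate(event_phases=[0.5], event_variances=[1e-3],
                                event_strengths=[1.0],
                                background_rate=1e-12, cycle_period=1.0)
        post = PhasePosterior(0.5, 4e-4)
        out = event_update(post, t)
        assert out.mean == pytest.approx(0.5, abs=1e-9)
        assert out.variance == pytest.approx(1.0 / (1 / 4e-4 + 1 / 1e-3),
                                             rel=1e-9)

    def test_symmetric_ambiguity_inflates_variance(self):
        # two equally weighted expectations symmetric about mu_t: the mean
        # is unchanged but variance grows above the conjugate update
        t = ExpectationTemplate(event_phases=[0.4, 0.6],
                                event_variances=[1e-3, 1e-3],
                                event_strengths=[0.5, 0.5],
                                background_rate=1e-12, cycle_period=1.0)
        post = PhasePosterior(0.5, 4e-4)
        out = event_update(post, t)
        conjugate = 1.0 / (1 / 4e-4 + 1 / 1e-3)
        assert out.mean == pytest.approx(0.5, abs=1e-12)
        assert out.variance > conjugate

    def test_matches_dense_grid_bayes_oracle(self, rng):
        # moment-matching against the exact one-event posterior
        # p(phi) ~ N(phi | mu, V) * lambda(phi) on a dense grid
        from pippet.domain import template_rate

        for _ in range(20):
            t, post = _random_state(rng, n_events=int(rng.integers(1, 4)))
            grid = np.linspace(post.mean - 1.5, post.mean + 1.5, 100_001)
            prior = np.exp(-0.5 * (grid - post.mean) ** 2 / post.variance)
            w = prior * template_rate(t, grid)
            w /= w.sum()
            mean = float((w * grid).sum())
            var = float((w * (grid - mean) ** 2).sum())
            out = event_update(post, t)
            assert abs(out.mean - mean) / abs(mean) < 1e-4
            assert abs(out.variance - var) / var < 1e-4


class TestRunPippet:
    def test_tracks_matching_isochronous_stimulus(self, quiet_config):
        stim = make_stimulus((500.0, 500.0), 5, event_noise=0.0)
        template = make_two_interval_template((1, 1), 1000.0).tiled(5)
        res = PippetModel(stim, template, quiet_config).filter()
        err = res.tracking_error()
        assert np.all(np.abs(err) < 10 * quiet_config.dt)

    def test_empty_stimulus_is_pure_drift(self, quiet_config):
        from pippet.domain import StimulusSequence

        stim = StimulusSequence(nominal_intervals=[1000.0], period=1000.0,
                                repetitions=1, event_times=[],
                                includes_final_event=False)
        template = _background_template()
        traj = run_pippet(stim, template, quiet_config, horizon=1.0)
        np.testing.assert_allclose(
            traj.posterior_means, traj.times + quiet_config.initial_mean,
            atol=1e-9)
        np.testing.assert_allclose(
            traj.posterior_variances,
            quiet_config.initial_variance
            + quiet_config.sigma ** 2 * traj.times, atol=1e-9)

    def test_mismatched_template_corrections_alternate_sign(self,
                                                            quiet_config):
        # 4:3 stimulus tracked with a 2:1-only template: the internal event
        # arrives early (correction forward), the cycle-start event then
        # arrives early relative to the shifted estimate (correction back)
        stim = make_stimulus((580.0, 420.0), 10, event_noise=0.0)
        template = make_two_interval_template(
            (2, 1), 1000.0, variance=2e-3).tiled(10)
        res = PippetModel(stim, template, quiet_config).filter()
        internal = res.phase_corrections[3::2]  # skip transient cycle
        starts = res.phase_corrections[4::2]
        assert np.all(internal > 0)
        assert np.all(starts < 0)

    def test_two_events_in_one_bin_rejected(self, quiet_config):
        from pippet.domain import StimulusSequence

        stim = StimulusSequence(nominal_intervals=[1000.0], period=1000.0,
                                repetitions=1,
                                event_times=[0.5, 0.5004],
                                includes_final_event=False)
        with pytest.raises(ValueError, match="dt"):
            PippetModel(stim, _background_template(), quiet_config)


class TestInvariants:
    def test_variance_positive_across_randomized_runs(self, rng):
        # randomized templates/stimuli with noise on: V stays positive
        cfg = FilterConfig.from_defaults(seed=7)
        for i in range(25):
            intervals = rng.uniform(250.0, 900.0, 2)
            stim = make_stimulus(intervals, 5, event_noise=0.02,
                                 seed=int(rng.integers(2**31)))
            template = make_two_interval_template(
                tuple(intervals), float(intervals.sum()),
                variance=float(rng.uniform(1e-4, 3e-3))).tiled(5)
            traj = run_pippet(stim, template, cfg,
                              rng=np.random.default_rng(i))
            assert np.all(traj.posterior_variances > 0)

    def test_noise_free_run_is_deterministic(self, quiet_config):
        stim = make_stimulus((580.0, 420.0), 5, event_noise=0.0)
        template = make_two_interval_template((2, 1), 1000.0).tiled(5)
        a = run_pippet(stim, template, quiet_config)
        b = run_pippet(stim, template, quiet_config)
        np.testing.assert_array_equal(a.posterior_means, b.posterior_means)
        np.testing.assert_array_equal(a.posterior_variances,
                                      b.posterior_variances)

    def test_shift_equivariance(self, quiet_config):
        # translating the template phases and the initial mean by delta
        # (a pure phase translation) shifts the whole mean trajectory by
        # exactly delta and leaves the variance trajectory unchanged
        delta = 0.25
        stim = make_stimulus((580.0, 420.0), 3, event_noise=0.0)
        template = make_two_interval_template((58, 42), 1000.0).tiled(3)
        base = run_pippet(stim, template, quiet_config)
        cfg = quiet_config.replace(
            initial_mean=quiet_config.initial_mean + delta)
        shifted = run_pippet(stim, template.shifted(delta), cfg)
        np.testing.assert_allclose(shifted.posterior_means,
                                   base.posterior_means + delta,
                                   atol=1e-12)
        np.testing.assert_allclose(shifted.posterior_variances,
                                   base.posterior_variances, atol=1e-12)

    def test_kernel_agrees_with_python_ops(self, quiet_config):
        # one dt step at a time through the python-level ops reproduces the
        # compiled trajectory
        stim = make_stimulus((500.0, 500.0), 1, event_noise=0.0)
        template = make_two_interval_template((1, 1), 1000.0).tiled(1)
        model = PippetModel(stim, template, quiet_config)
        traj = model.filter().trajectory
        post = PhasePosterior(quiet_config.initial_mean,
                              quiet_config.initial_variance)
        event_steps = set(model.event_steps.tolist())
        for k in range(model.n_steps):
            post = drift_step(post, template, quiet_config,
                              event_occurred=k in event_steps)
            assert post.mean == pytest.approx(traj.posterior_means[k + 1],
                                              abs=1e-12)
            assert post.variance == pytest.approx(
                traj.posterior_variances[k + 1], abs=1e-12)
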