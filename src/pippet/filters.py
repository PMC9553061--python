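"""Single-template phase inference (the PIPPET filter).

The filter maintains a Gaussian posterior on phase (mean mu_t, variance
V_t).  Between events the mean drifts at the nominal rate and the variance
accumulates sigma^2 per second; when an event arrives the posterior is
reset to a precision-weighted combination of the current estimate and the
template's expected event phases.  The continuous part and the event reset
are both expressed through one Euler step of the stochastic differential
equation

    d(mu) = dt + (mu_hat - mu_t) (dN_t - Lam dt) + eta_mu sqrt(dt) z
    dV    = sigma^2 dt + (V_hat - V_t) (dN_t - Lam dt)

where Lam is the subjective hazard rate and (mu_hat, V_hat) the would-be
reset moments.  The total hazard includes the background term,
Lam = lambda_0 + sum_i Lam_i, which is what makes the reset weights
lambda_0/Lam and Lam_i/Lam sum to one.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .domain import (ExpectationTemplate, FilterConfig, FilterTrajectory,
                     PhasePosterior, StimulusSequence)

__all__ = ["hazard", "drift_step", "event_update", "run_pippet",
           "PippetModel", "PippetResults"]


def hazard(template: ExpectationTemplate, posterior: PhasePosterior):
    """Subjective hazard rate at the current posterior.

    Returns ``(Lam, Lam_i)``: the per-expectation hazards
    Lam_i = lambda_i N(mu_t | phi_i, v_i + V_t) and their total including
    the background, Lam = lambda_0 + sum_i Lam_i.
    """
    mu, V = posterior.mean, posterior.variance
    s = template.event_variances + V
    d = mu - template.event_phases
    lam_i = template.event_strengths * np.exp(-0.5 * d * d / s) \
        / np.sqrt(2.0 * np.pi * s)
    return template.background_rate + float(lam_i.sum()), lam_i


def event_update(posterior: PhasePosterior,
                 template: ExpectationTemplate) -> PhasePosterior:
    """Posterior reset at an observed event.

    Moment-matches the exact one-event Bayesian posterior
    p(phi) proportional to N(phi | mu_t, V_t) lambda(phi): each expectation i
    contributes a conjugate Gaussian update (mu_hat_i, V_hat_i) weighted by
    Lam_i / Lam, and the background contributes the unchanged prior
    weighted by lambda_0 / Lam.
    """
    mu, V = posterior.mean, posterior.variance
    Lam, lam_i = hazard(template, posterior)
    prec = 1.0 / V + 1.0 / template.event_variances
    mu_i = (mu / V + template.event_phases / template.event_variances) / prec
    V_i = 1.0 / prec
    lam0 = template.background_rate
    mu_hat = (lam0 * mu + float((lam_i * mu_i).sum())) / Lam
    V_hat = (lam0 * (V + (mu - mu_hat) ** 2)
             + float((lam_i * (V_i + (mu_i - mu_hat) ** 2)).sum())) / Lam
    return PhasePosterior(mean=mu_hat, variance=V_hat)


def drift_step(posterior: PhasePosterior, template: ExpectationTemplate,
               config: FilterConfig, event_occurred: bool,
               noise: float = 0.0) -> PhasePosterior:
    """One Euler step of the filter SDE.

    ``noise`` is the standard-normal deviate z for the phase-tracking
    perturbation (0 reproduces the noise-free filter).  With only the
    background expected (no Gaussian components near mu), mu_hat = mu and
    V_hat = V, so the step reduces to pure drift-diffusion.
    """
    dt = config.dt
    mu, V = posterior.mean, posterior.variance
    Lam, _ = hazard(template, posterior)
    reset = event_update(posterior, template)
    dN = 1.0 if event_occurred else 0.0
    w = dN - Lam * dt
    mu_new = mu + dt + (reset.mean - mu) * w \
        + config.phase_noise_scale * np.sqrt(dt) * noise
    V_new = V + config.sigma ** 2 * dt + (reset.variance - V) * w
    if not (np.isfinite(mu_new) and np.isfinite(V_new)):
        raise FloatingPointError(
            "filter state became non-finite (dt too large?)")
    return PhasePosterior(mean=mu_new,
                          variance=max(V_new, _kernels.V_FLOOR))


def _event_grid_steps(event_times: np.ndarray, dt: float,
                      n_steps: int) -> np.ndarray:
    """Map event times to nearest dt grid steps; reject bin collisions."""
    steps = np.rint(np.asarray(event_times, dtype=float) / dt).astype(np.int64)
    if steps.size and (steps.min() < 0 or steps.max() >= n_steps):
        raise ValueError("event times fall outside the simulated horizon")
    if steps.size > 1 and np.any(np.diff(steps) == 0):
        raise ValueError("two events map to one dt bin (dt too coarse)")
    return steps


class PippetModel:
    """Phase-inference model for one stimulus under one expectation template.

    Parameters
    ----------
    stimulus : StimulusSequence
        Realized event times (already carrying any event-timing noise).
    template : ExpectationTemplate
        Event expectations; for multi-repetition stimuli pass a template
        tiled over the tracked repetitions (``ExpectationTemplate.tiled``).
    config : FilterConfig
        Time step, diffusion rate, noise scales and initial posterior.
    horizon : float, optional
        Simulated duration in seconds; defaults to one step past the last
        stimulus event.
    """

    def __init__(self, stimulus: StimulusSequence,
                 template: ExpectationTemplate,
                 config: FilterConfig | None = None,
                 horizon: float | None = None):
        self.stimulus = stimulus
        self.template = template
        self.config = config if config is not None else FilterConfig()
        if horizon is None:
            last = stimulus.event_times[-1] if stimulus.event_times.size \
                else stimulus.duration
            horizon = last + self.config.dt
        self.n_steps = int(np.ceil(horizon / self.config.dt)) + 1
        self.event_steps = _event_grid_steps(
            stimulus.event_times, self.config.dt, self.n_steps)

    def filter(self, rng: np.random.Generator | None = None
               ) -> "PippetResults":
        """Run the filter and return the results object."""
        cfg = self.config
        if cfg.phase_noise_scale > 0:
            if rng is None:
                rng = np.random.default_rng(cfg.seed)
            noise = rng.standard_normal(self.n_steps)
        else:
            noise = np.zeros(self.n_steps)
        mu, V, Lam, corr, preV, floor_hits = _kernels.pippet_kernel(
            self.n_steps, cfg.dt, cfg.initial_mean, cfg.initial_variance,
            cfg.sigma, cfg.phase_noise_scale, noise,
            self.template.event_phases, self.template.event_variances,
            self.template.event_strengths, self.template.background_rate,
            self.event_steps)
        flags = np.zeros(self.n_steps + 1, dtype=bool)
        flags[self.event_steps] = True
        traj = FilterTrajectory(
            times=np.arange(self.n_steps + 1) * cfg.dt,
            posterior_means=mu, posterior_variances=V, total_hazard=Lam,
            event_flags=flags, event_times=self.stimulus.event_times,
            phase_corrections=corr, pre_event_variances=preV,
            variance_floor_hits=int(floor_hits))
        return PippetResults(self, traj)

    fit = filter  # statsmodels-style alias


class PippetResults:
    """Results of a PippetModel run: the trajectory plus event summaries."""

    def __init__(self, model: PippetModel, trajectory: FilterTrajectory):
        self.model = model
        self.trajectory = trajectory

    @property
    def posterior_means(self) -> np.ndarray:
        return self.trajectory.posterior_means

    @property
    def posterior_variances(self) -> np.ndarray:
        return self.trajectory.posterior_variances

    @property
    def phase_corrections(self) -> np.ndarray:
        """Per-event reset magnitude mu_t+ - mu_t."""
        return self.trajectory.phase_corrections

    @property
    def pre_event_variances(self) -> np.ndarray:
        """V_t on the time step preceding each event."""
        return self.trajectory.pre_event_variances

    def tracking_error(self) -> np.ndarray:
        """mu_t - t at each event step (0 for perfect tracking)."""
        steps = self.model.event_steps
        mu = self.trajectory.posterior_means[steps]
        return mu - steps * self.model.config.dt

    def post_event_means(self) -> np.ndarray:
        """Posterior mean right after each event (state at step k + 1)."""
        return self.trajectory.posterior_means[self.model.event_steps + 1]

    def to_dataframe(self):
        return self.trajectory.to_dataframe()

    def summary(self) -> str:
        c = self.phase_corrections
        template = getattr(self.model, "template", None)
        name = template.label if template is not None else \
            f"bank of {len(self.model.bank)}"
        lines = [
            "PIPPET filter results",
            "=" * 44,
            f"template:            {name or '(unnamed)'}",
            f"events observed:     {self.model.event_steps.size}",
            f"steps (dt={self.model.config.dt:g}s): {self.model.n_steps}",
            f"mean phase corr.:    {c.mean():+.5f} s" if c.size else
            "mean phase corr.:    n/a",
            f"mean |phase corr.|:  {np.abs(c).mean():.5f} s" if c.size else
            "mean |phase corr.|:  n/a",
            f"mean pre-event V:    {self.pre_event_variances.mean():.6f}"
            if c.size else "mean pre-event V:    n/a",
            f"final posterior:     mu={self.posterior_means[-1]:.4f}, "
            f"V={self.posterior_variances[-1]:.6f}",
            f"variance floor hits: {self.trajectory.variance_floor_hits}",
        ]
        return "\n".join(lines)


def run_pippet(stimulus: StimulusSequence, template: ExpectationTemplate,
               config: FilterConfig | None = None,
               rng: np.random.Generator | None = None,
               horizon: float | None = None) -> FilterTrajectory:
    """Functional wrapper: run the single-template filter, return trajectory."""
    return PippetModel(stimulus, template, config,
                       horizon=horizon).filter(rng=rng).trajectory
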