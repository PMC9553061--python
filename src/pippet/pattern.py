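"""Pattern inference over a bank of expectation templates (pPIPPET).

A single Gaussian posterior on phase is shared across templates.  At each
step the filter computes, per template m, the candidate hazard Lam^m and
candidate reset moments (mu_hat^m, V_hat^m) from the shared posterior, then
updates the template probabilities from the hazard ratios,

    dp^m = p^m (Lam^m / Lam - 1) (dN_t - Lam dt),   Lam = sum_m p^m Lam^m,

and marginalizes the candidates into a single Gaussian via mixture moments.
An event at a time only one template anticipates raises that template's
probability; an event all templates anticipate equally leaves the
distribution unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .domain import (FilterConfig, FilterTrajectory, PhasePosterior,
                     StimulusSequence, TemplateBank)
from .filters import PippetResults, _event_grid_steps

__all__ = ["PatternPosterior", "update_template_probs",
           "marginalize_posterior", "posterior_entropy", "run_ppippet",
           "PatternPippetModel", "PatternPippetResults"]


def posterior_entropy(probs) -> float:
    """Shannon entropy of a discrete distribution, in bits (0 log 0 = 0)."""
    p = np.asarray(probs, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass(frozen=True)
class PatternPosterior:
    """Discrete posterior over templates: probabilities and their entropy."""

    probs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if np.any(self.probs < 0):
            raise ValueError("template probabilities must be >= 0")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("template probabilities must sum to 1")

    @property
    def entropy(self) -> float:
        """Entropy in bits."""
        return posterior_entropy(self.probs)

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.probs))


def update_template_probs(probs, per_template_hazards, total_hazard,
                          dN: float, dt: float) -> np.ndarray:
    """One Euler step of the template-probability update.

    ``total_hazard`` must be the probability-weighted total
    Lam = sum_m p^m Lam^m.  Probabilities that the Euler step drives
    negative are clipped to 0 and the vector renormalized.
    """
    p = np.asarray(probs, dtype=float)
    lam_m = np.asarray(per_template_hazards, dtype=float)
    p_new = p + p * (lam_m / total_hazard - 1.0) * (dN - total_hazard * dt)
    p_new = np.clip(p_new, 0.0, None)
    return p_new / p_new.sum()


def marginalize_posterior(probs, means, variances) -> PhasePosterior:
    """Moment-match the mixture of per-template candidate posteriors.

    Uses the numerically stable centred form
    V_hat = sum_m p^m (V_hat^m + (mu_hat^m - mu_hat)^2), which is
    algebraically identical to sum_m p^m (V^m + (mu^m)^2) - mu_hat^2.
    """
    p = np.asarray(probs, dtype=float)
    mu_m = np.asarray(means, dtype=float)
    V_m = np.asarray(variances, dtype=float)
    mu_hat = float((p * mu_m).sum())
    V_hat = float((p * (V_m + (mu_m - mu_hat) ** 2)).sum())
    return PhasePosterior(mean=mu_hat, variance=max(V_hat, _kernels.V_FLOOR))


class PatternPippetModel:
    """Joint phase and pattern inference for one stimulus under a bank.

    Parameters mirror :class:`~pippet.filters.PippetModel`, with a
    :class:`~pippet.domain.TemplateBank` in place of a single template.
    ``tile_repetitions`` tiles every bank template over that many cycles
    (plus the shared closing onset) before filtering, matching a stimulus
    of repeated cycles.
    """

    def __init__(self, stimulus: StimulusSequence, bank: TemplateBank,
                 config: FilterConfig | None = None,
                 horizon: float | None = None,
                 tile_repetitions: int | None = None):
        self.stimulus = stimulus
        self.bank = bank
        self.config = config if config is not None else FilterConfig()
        templates = bank.templates
        if tile_repetitions is not None and tile_repetitions > 1:
            templates = tuple(t.tiled(tile_repetitions) for t in templates)
        self.templates = templates
        if horizon is None:
            last = stimulus.event_times[-1] if stimulus.event_times.size \
                else stimulus.duration
            horizon = last + self.config.dt
        self.n_steps = int(np.ceil(horizon / self.config.dt)) + 1
        self.event_steps = _event_grid_steps(
            stimulus.event_times, self.config.dt, self.n_steps)
        # flatten the ragged per-template event arrays for the kernel
        counts = np.array([t.n_events for t in templates], dtype=np.int64)
        self._indptr = np.concatenate(([0], np.cumsum(counts)))
        self._phases = np.concatenate([t.event_phases for t in templates])
        self._variances = np.concatenate(
            [t.event_variances for t in templates])
        self._strengths = np.concatenate(
            [t.event_strengths for t in templates])
        lam0s = {t.background_rate for t in templates}
        if len(lam0s) != 1:
            raise ValueError(
                "bank templates must share a single background rate")
        self._lam0 = lam0s.pop()

    def filter(self, rng: np.random.Generator | None = None
               ) -> "PatternPippetResults":
        cfg = self.config
        if cfg.phase_noise_scale > 0:
            if rng is None:
                rng = np.random.default_rng(cfg.seed)
            noise = rng.standard_normal(self.n_steps)
        else:
            noise = np.zeros(self.n_steps)
        (mu, V, Lam, probs, hazards, corr, preV,
         floor_hits) = _kernels.ppippet_kernel(
            self.n_steps, cfg.dt, cfg.initial_mean, cfg.initial_variance,
            cfg.sigma, cfg.phase_noise_scale, noise,
            self._phases, self._variances, self._strengths, self._indptr,
            self._lam0, self.bank.prior_probs.astype(float),
            self.event_steps)
        flags = np.zeros(self.n_steps + 1, dtype=bool)
        flags[self.event_steps] = True
        traj = FilterTrajectory(
            times=np.arange(self.n_steps + 1) * cfg.dt,
            posterior_means=mu, posterior_variances=V, total_hazard=Lam,
            event_flags=flags, event_times=self.stimulus.event_times,
            phase_corrections=corr, pre_event_variances=preV,
            template_probs=probs, template_labels=list(self.bank.labels),
            variance_floor_hits=int(floor_hits))
        return PatternPippetResults(self, traj, hazards)

    fit = filter


class PatternPippetResults(PippetResults):
    """Results of a PatternPippetModel run."""

    def __init__(self, model: PatternPippetModel,
                 trajectory: FilterTrajectory, hazards: np.ndarray):
        super().__init__(model, trajectory)
        self.template_hazards = hazards  # (n_steps + 1, M) candidate hazards

    @property
    def template_probs(self) -> np.ndarray:
        return self.trajectory.template_probs

    @property
    def final_pattern_posterior(self) -> PatternPosterior:
        return PatternPosterior(self.template_probs[-1])

    @property
    def map_template_index(self) -> int:
        return self.final_pattern_posterior.argmax

    @property
    def map_template(self):
        return self.model.bank.templates[self.map_template_index]

    @property
    def final_entropy(self) -> float:
        """Entropy (bits) of the final posterior over templates."""
        return self.final_pattern_posterior.entropy

    def summary(self) -> str:
        p = self.final_pattern_posterior
        labels = self.model.bank.labels
        order = np.argsort(p.probs)[::-1][:5]
        top = ", ".join(f"{labels[m]}={p.probs[m]:.3f}" for m in order)
        return (super().summary()
                + f"\ntemplates:           {len(self.model.bank)}"
                + f"\nMAP template:        {labels[p.argmax]}"
                + f"\nposterior entropy:   {p.entropy:.3f} bits"
                + f"\ntop probabilities:   {top}")


def run_ppippet(stimulus: StimulusSequence, bank: TemplateBank,
                config: FilterConfig | None = None,
                rng: np.random.Generator | None = None,
                horizon: float | None = None,
                tile_repetitions: int | None = None) -> FilterTrajectory:
    """Functional wrapper: run pattern inference, return the trajectory."""
    return PatternPippetModel(
        stimulus, bank, config, horizon=horizon,
        tile_repetitions=tile_repetitions).filter(rng=rng).trajectory
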