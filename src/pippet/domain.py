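"""Core data types shared by the filters, prior builders and experiments.

Phase is measured in seconds: the tracked phase variable advances at a
nominal rate of 1 per second of stimulus time, so event phases and event
times share a scale.  Stimulus-facing interval fields are kept in
milliseconds (the unit rhythm-perception studies report); realized event
times are seconds.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpectationTemplate",
    "TemplateBank",
    "PhasePosterior",
    "FilterConfig",
    "StimulusSequence",
    "FilterTrajectory",
    "template_rate",
    "make_two_interval_template",
    "load_defaults",
]

MS = 1e-3  # milliseconds -> seconds


def load_defaults() -> dict:
    """Load the versioned default-parameter file shipped with the package."""
    ref = importlib.resources.files("pippet").joinpath("defaults.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ExpectationTemplate:
    """One rhythmic pattern's event expectations over phase.

    The expectation template is an inhomogeneous point-process rate over
    phase: a uniform background ``background_rate`` (lambda_0) plus one
    Gaussian bump per expected event, centred at ``event_phases[i]`` with
    variance ``event_variances[i]`` and mass ``event_strengths[i]``.

    Parameters
    ----------
    event_phases : array of float
        Mean phases phi_i (seconds) of expected events, strictly increasing,
        all within ``[0, cycle_period]``.
    event_variances : array of float
        Variances v_i (s^2) of each expectation; 1/v_i is its precision.
    event_strengths : array of float
        Strengths lambda_i >= 0 (expected events per unit phase mass).
    background_rate : float
        lambda_0 > 0, the rate of events from uniform background noise.
    cycle_period : float
        Duration of one pattern cycle (seconds).
    label : str
        Pattern identifier, e.g. ``"2:1:1"``.
    """

    event_phases: np.ndarray
    event_variances: np.ndarray
    event_strengths: np.ndarray
    background_rate: float
    cycle_period: float
    label: str = ""

    def __post_init__(self):
        for name in ("event_phases", "event_variances", "event_strengths"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        n = self.event_phases.size
        if not (n >= 1 and self.event_variances.size == n
                and self.event_strengths.size == n):
            raise ValueError("event arrays must have equal length >= 1")
        if not np.all(self.event_variances > 0):
            raise ValueError("all event variances must be > 0")
        if not np.all(self.event_strengths >= 0):
            raise ValueError("event strengths must be >= 0")
        if not self.background_rate > 0:
            raise ValueError("background_rate must be > 0")
        if not self.cycle_period > 0:
            raise ValueError("cycle_period must be > 0")
        if n > 1 and not np.all(np.diff(self.event_phases) > 0):
            raise ValueError("event phases must be strictly increasing")
        if self.event_phases[0] < 0 or self.event_phases[-1] > self.cycle_period:
            raise ValueError("event phases must lie in [0, cycle_period]")

    @property
    def n_events(self) -> int:
        return self.event_phases.size

    def rate(self, phase):
        """Evaluate the expectation template lambda(phi) at ``phase``."""
        return template_rate(self, phase)

    def tiled(self, repetitions: int, include_final: bool = True
              ) -> "ExpectationTemplate":
        """Tile the cycle's events across ``repetitions`` cycles.

        Event phases are shifted by k * cycle_period for k = 0..reps-1; the
        template stays aperiodic (phase advances along the real line), so
        tiling keeps the filter equations unchanged.  ``include_final`` adds
        the shared cycle-start event that closes the last cycle.
        """
        if repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        offsets = np.arange(repetitions) * self.cycle_period
        phases = (self.event_phases[None, :] + offsets[:, None]).ravel()
        variances = np.tile(self.event_variances, repetitions)
        strengths = np.tile(self.event_strengths, repetitions)
        if include_final and not math.isclose(
                self.event_phases[-1], self.cycle_period):
            phases = np.append(phases, repetitions * self.cycle_period)
            variances = np.append(variances, self.event_variances[0])
            strengths = np.append(strengths, self.event_strengths[0])
        return ExpectationTemplate(
            event_phases=phases,
            event_variances=variances,
            event_strengths=strengths,
            background_rate=self.background_rate,
            cycle_period=repetitions * self.cycle_period,
            label=self.label,
        )

    def shifted(self, delta: float) -> "ExpectationTemplate":
        """Translate all event phases by ``delta`` (for equivariance checks)."""
        # bypass validation: a negative delta may push phases below zero,
        # which is fine on the real line the filter tracks
        shifted = ExpectationTemplate.__new__(ExpectationTemplate)
        object.__setattr__(shifted, "event_phases", self.event_phases + delta)
        object.__setattr__(shifted, "event_variances", self.event_variances)
        object.__setattr__(shifted, "event_strengths", self.event_strengths)
        object.__setattr__(shifted, "background_rate", self.background_rate)
        object.__setattr__(shifted, "cycle_period",
                           self.cycle_period + max(delta, 0.0))
        object.__setattr__(shifted, "label", self.label)
        return shifted

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "cycle_period": self.cycle_period,
            "background_rate": self.background_rate,
            "event_phases": self.event_phases.tolist(),
            "event_variances": self.event_variances.tolist(),
            "event_strengths": self.event_strengths.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExpectationTemplate":
        return cls(
            event_phases=np.asarray(d["event_phases"], dtype=float),
            event_variances=np.asarray(d["event_variances"], dtype=float),
            event_strengths=np.asarray(d["event_strengths"], dtype=float),
            background_rate=float(d["background_rate"]),
            cycle_period=float(d["cycle_period"]),
            label=str(d.get("label", "")),
        )


def template_rate(template: ExpectationTemplate, phase):
    """Point-process rate lambda(phi) = lambda_0 + sum_i lambda_i N(phi | phi_i, v_i).

    ``phase`` may be a scalar or an array; the return matches its shape.
    """
    phi = np.asarray(phase, dtype=float)
    d = phi[..., None] - template.event_phases
    v = template.event_variances
    dens = np.exp(-0.5 * d * d / v) / np.sqrt(2.0 * np.pi * v)
    out = template.background_rate + (template.event_strengths * dens).sum(axis=-1)
    return float(out) if np.isscalar(phase) or phi.ndim == 0 else out


def make_two_interval_template(ratio, period_ms: float, *,
                               strength: float | None = None,
                               variance: float | None = None,
                               background_rate: float | None = None,
                               label: str | None = None
                               ) -> ExpectationTemplate:
    """Template for a cyclic two-interval rhythm of a given ratio.

    A cycle of a two-interval rhythm carries the cycle-start onset plus one
    internal onset at ``r1 / (r1 + r2)`` of the period (the closing onset is
    the next cycle's start).  ``ratio`` is a pair like ``(2, 1)`` or
    ``(58, 42)``.
    """
    r1, r2 = float(ratio[0]), float(ratio[1])
    if r1 <= 0 or r2 <= 0 or period_ms <= 0:
        raise ValueError("ratio components and period must be positive")
    defaults = load_defaults()["templates"]
    strength = defaults["strength"] if strength is None else strength
    variance = defaults["variance_even"] if variance is None else variance
    background_rate = (defaults["background_rate"]
                       if background_rate is None else background_rate)
    period = period_ms * MS
    internal = r1 / (r1 + r2) * period
    if label is None:
        label = f"{ratio[0]:g}:{ratio[1]:g}"
    return ExpectationTemplate(
        event_phases=np.array([0.0, internal]),
        event_variances=np.array([variance, variance]),
        event_strengths=np.array([strength, strength]),
        background_rate=background_rate,
        cycle_period=period,
        label=label,
    )


@dataclass(frozen=True)
class TemplateBank:
    """A discrete prior over expectation templates.

    ``prior_probs[m]`` is p0^m, the prior probability that template m
    generates the stimulus.  ``max_strength`` (lambda_max), ``max_variance``
    (v_max) and ``restriction_size`` (N) record how the bank was
    parameterized.
    """

    templates: tuple
    prior_probs: np.ndarray
    max_strength: float = 1.0
    max_variance: float = 0.002
    restriction_size: int = 22

    def __post_init__(self):
        object.__setattr__(self, "templates", tuple(self.templates))
        object.__setattr__(
            self, "prior_probs", np.asarray(self.prior_probs, dtype=float))
        if len(self.templates) != self.prior_probs.size:
            raise ValueError("one prior probability per template required")
        if np.any(self.prior_probs < 0):
            raise ValueError("prior probabilities must be >= 0")
        if abs(self.prior_probs.sum() - 1.0) > 1e-9:
            raise ValueError("prior probabilities must sum to 1")

    def __len__(self) -> int:
        return len(self.templates)

    @property
    def labels(self) -> list:
        return [t.label for t in self.templates]

    def interval_vectors(self) -> np.ndarray:
        """Per-template interval vectors (ms), closing the cycle."""
        rows = []
        for t in self.templates:
            phases = np.append(t.event_phases, t.cycle_period)
            rows.append(np.diff(phases) / MS)
        return np.asarray(rows)

    def to_json(self, path) -> None:
        payload = {
            "max_strength": self.max_strength,
            "max_variance": self.max_variance,
            "restriction_size": self.restriction_size,
            "prior_probs": self.prior_probs.tolist(),
            "templates": [t.to_dict() for t in self.templates],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TemplateBank":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            templates=tuple(ExpectationTemplate.from_dict(d)
                            for d in payload["templates"]),
            prior_probs=np.asarray(payload["prior_probs"], dtype=float),
            max_strength=float(payload["max_strength"]),
            max_variance=float(payload["max_variance"]),
            restriction_size=int(payload["restriction_size"]),
        )

    def to_csv(self, path) -> None:
        """Flat CSV: one row per event expectation."""
        rows = []
        for m, (t, p) in enumerate(zip(self.templates, self.prior_probs)):
            for i in range(t.n_events):
                rows.append({
                    "template_index": m,
                    "label": t.label,
                    "prior_prob": p,
                    "cycle_period": t.cycle_period,
                    "background_rate": t.background_rate,
                    "event_index": i,
                    "phase": t.event_phases[i],
                    "variance": t.event_variances[i],
                    "strength": t.event_strengths[i],
                })
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, *, max_strength=1.0, max_variance=0.002,
                 restriction_size=22) -> "TemplateBank":
        df = pd.read_csv(path)
        templates, priors = [], []
        for m, grp in df.groupby("template_index", sort=True):
            grp = grp.sort_values("event_index")
            templates.append(ExpectationTemplate(
                event_phases=grp["phase"].to_numpy(),
                event_variances=grp["variance"].to_numpy(),
                event_strengths=grp["strength"].to_numpy(),
                background_rate=float(grp["background_rate"].iloc[0]),
                cycle_period=float(grp["cycle_period"].iloc[0]),
                label=str(grp["label"].iloc[0]),
            ))
            priors.append(float(grp["prior_prob"].iloc[0]))
        return cls(templates=tuple(templates),
                   prior_probs=np.asarray(priors),
                   max_strength=max_strength, max_variance=max_variance,
                   restriction_size=restriction_size)


@dataclass(frozen=True)
class PhasePosterior:
    """Gaussian belief over phase at one time point: mean mu, variance V."""

    mean: float
    variance: float

    def __post_init__(self):
        if not self.variance > 0:
            raise ValueError("posterior variance must be > 0")


@dataclass(frozen=True)
class FilterConfig:
    """Run configuration for the phase-inference filters.

    ``sigma`` is the expected phase diffusion rate (part of the observer's
    generative model); ``event_noise_scale`` (eta_e) and
    ``phase_noise_scale`` (eta_mu) are implementation noise - properties of
    the simulated listener, not of the generative model.  eta_mu perturbs
    d(mu) by eta_mu * sqrt(dt) * z per step so its effect per unit time is
    dt-invariant.
    """

    dt: float = 0.001
    sigma: float = 0.02
    event_noise_scale: float = 0.02
    phase_noise_scale: float = 0.03
    initial_mean: float = 0.0
    initial_variance: float = 0.0002
    seed: int = 0

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.initial_variance > 0:
            raise ValueError("initial_variance must be > 0")

    @classmethod
    def from_defaults(cls, **overrides) -> "FilterConfig":
        params = dict(load_defaults()["filter"])
        params.update(overrides)
        return cls(**params)

    def replace(self, **changes) -> "FilterConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class StimulusSequence:
    """Ordered event times with cycle structure.

    ``nominal_intervals`` and ``period`` are in ms; ``event_times`` are the
    realized onset times in seconds (including any noise perturbation).
    """

    nominal_intervals: np.ndarray
    period: float
    repetitions: int
    event_times: np.ndarray
    includes_final_event: bool = True

    def __post_init__(self):
        object.__setattr__(self, "nominal_intervals",
                           np.asarray(self.nominal_intervals, dtype=float))
        object.__setattr__(self, "event_times",
                           np.asarray(self.event_times, dtype=float))
        if abs(self.nominal_intervals.sum() - self.period) > 1e-6:
            raise ValueError("nominal intervals must sum to the period")
        if self.event_times.size > 1 and not np.all(
                np.diff(self.event_times) > 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def duration(self) -> float:
        """Nominal stimulus duration in seconds."""
        return self.repetitions * self.period * MS

    def cycle_indices(self) -> np.ndarray:
        """Cycle index of each event under the nominal (noise-free) layout."""
        per_cycle = self.nominal_intervals.size
        idx = np.arange(self.event_times.size)
        cyc = idx // per_cycle
        if self.includes_final_event:
            cyc = np.minimum(cyc, self.repetitions - 1)
        return cyc

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "onset_ms": self.event_times / MS,
            "cycle_index": self.cycle_indices(),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, *, nominal_intervals, period, repetitions,
                 includes_final_event=True) -> "StimulusSequence":
        df = pd.read_csv(path)
        return cls(nominal_intervals=nominal_intervals, period=period,
                   repetitions=repetitions,
                   event_times=df["onset_ms"].to_numpy() * MS,
                   includes_final_event=includes_final_event)


@dataclass
class FilterTrajectory:
    """Time-indexed record of a filter run.

    Arrays are aligned on the dt grid (state *before* each step); per-event
    fields are aligned with the stimulus events.  ``phase_corrections`` are
    mu_t+ - mu_t, the reset applied at each event.  ``template_probs`` is
    None for the single-template filter.
    """

    times: np.ndarray
    posterior_means: np.ndarray
    posterior_variances: np.ndarray
    total_hazard: np.ndarray
    event_flags: np.ndarray
    event_times: np.ndarray
    phase_corrections: np.ndarray
    pre_event_variances: np.ndarray
    template_probs: np.ndarray | None = None
    template_labels: list | None = None
    variance_floor_hits: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time": self.times,
            "mu": self.posterior_means,
            "V": self.posterior_variances,
            "Lambda": self.total_hazard,
            "event_flag": self.event_flags.astype(int),
        })
        if self.template_probs is not None:
            labels = (self.template_labels
                      or [str(m) for m in range(self.template_probs.shape[1])])
            for j, lab in enumerate(labels):
                df[f"p_m_{lab}"] = self.template_probs[:, j]
            p = np.clip(self.template_probs, 1e-300, None)
            df["entropy"] = -(self.template_probs * np.log2(p)).sum(axis=1)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)
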