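"""Three-interval rhythm space: grids, stimuli and simplex geometry.

A three-interval rhythm is a cyclic pattern of three inter-onset intervals
(d1, d2, d3) summing to a fixed period, each at least a minimum duration.
The constrained set is a triangle (2-simplex slice); utilities here
enumerate it on a grid, sample it uniformly, turn interval triples into
event-time stimuli, and handle cyclic-rotation equivalence of ratio labels.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .domain import MS, StimulusSequence

__all__ = ["enumerate_simplex", "simplex_count", "sample_uniform_rhythms",
           "make_stimulus", "cyclic_class", "simplex_coords",
           "nearest_small_integer_ratio"]

log = logging.getLogger(__name__)


def simplex_count(total: float, min_interval: float, resolution: float) -> int:
    """Closed-form (stars-and-bars) size of the constrained grid."""
    slack = int(round((total - 3 * min_interval) / resolution))
    if slack < 0:
        return 0
    return (slack + 2) * (slack + 1) // 2


def enumerate_simplex(total: float, min_interval: float,
                      resolution: float) -> np.ndarray:
    """All grid triples (d1, d2, d3) of multiples of ``resolution`` that
    sum to ``total`` with every interval >= ``min_interval``.

    Units are arbitrary but conventionally ms.  Returns an (n, 3) array;
    n follows the stars-and-bars closed form.
    """
    for name, v in (("total", total), ("min_interval", min_interval)):
        if abs(v / resolution - round(v / resolution)) > 1e-9:
            raise ValueError(f"resolution must divide {name}")
    t = int(round(total / resolution))
    m = int(round(min_interval / resolution))
    triples = []
    for a in range(m, t - 2 * m + 1):
        for b in range(m, t - a - m + 1):
            triples.append((a, b, t - a - b))
    out = np.asarray(triples, dtype=float) * resolution
    return out.reshape(-1, 3)


def sample_uniform_rhythms(k: int, total: float, min_interval: float,
                           seed=None) -> np.ndarray:
    """``k`` triples uniform on the continuous constrained simplex.

    A Dirichlet(1, 1, 1) draw is affinely mapped onto the feasible region
    (each interval >= ``min_interval``), which preserves uniformity.
    """
    if 3 * min_interval > total:
        raise ValueError("infeasible constraints: 3 * min_interval > total")
    rng = np.random.default_rng(seed)
    slack = total - 3 * min_interval
    w = rng.dirichlet(np.ones(3), size=k)
    return min_interval + w * slack


def make_stimulus(intervals, repetitions: int, event_noise: float = 0.0,
                  seed=None, period: float | None = None,
                  include_final: bool = True,
                  max_resample: int = 100) -> StimulusSequence:
    """Tile an interval pattern over repetitions and perturb onset times.

    ``intervals`` are in ms; ``event_noise`` (eta_e) is the SD in seconds of
    the i.i.d. normal perturbation applied to every onset except the first,
    which anchors the time origin at 0.  Perturbations that would reorder
    events are re-drawn (rejection preserves marginal normality conditional
    on the order); redraws are logged.
    """
    intervals = np.asarray(intervals, dtype=float)
    if np.any(intervals <= 0):
        raise ValueError("intervals must be positive")
    if period is None:
        period = float(intervals.sum())
    offsets = np.concatenate(([0.0], np.cumsum(intervals)[:-1])) * MS
    period_s = period * MS
    onsets = (offsets[None, :]
              + np.arange(repetitions)[:, None] * period_s).ravel()
    if include_final:
        onsets = np.append(onsets, repetitions * period_s)
    if event_noise > 0:
        gap = np.diff(onsets).min()
        if gap / (event_noise * math.sqrt(2.0)) < 2.326:  # >1% swap chance
            log.warning(
                "event noise %.4fs is large relative to the minimum "
                "inter-onset gap %.4fs; expect frequent reorderings",
                event_noise, gap)
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(onsets.size)
        z[0] = 0.0
        perturbed = onsets + event_noise * z
        redraws = 0
        for _ in range(max_resample):
            bad = np.flatnonzero(np.diff(perturbed) <= 0)
            if bad.size == 0:
                break
            idx = np.unique(np.concatenate((bad, bad + 1)))
            idx = idx[idx > 0]
            z[idx] = rng.standard_normal(idx.size)
            perturbed[idx] = onsets[idx] + event_noise * z[idx]
            redraws += idx.size
        else:
            raise RuntimeError("could not order perturbed onsets "
                               "(event noise too large)")
        if redraws:
            log.debug("resampled %d onset perturbations to keep order",
                      redraws)
        onsets = perturbed
    return StimulusSequence(
        nominal_intervals=intervals, period=period, repetitions=repetitions,
        event_times=onsets, includes_final_event=include_final)


def _parse_ratio(label):
    if isinstance(label, str):
        parts = tuple(int(x) for x in label.split(":"))
    else:
        parts = tuple(int(x) for x in label)
    if len(parts) != 3 or any(p <= 0 for p in parts):
        raise ValueError(f"not a valid three-part ratio: {label!r}")
    return parts


def cyclic_class(ratio_label) -> str:
    """Canonical representative of a ratio label under cyclic rotation.

    The representative is the lexicographically smallest rotation of the
    gcd-reduced integer triple, e.g. ``"1:2:1" -> "1:1:2"`` and
    ``"3:3:2" -> "2:3:3"``.  Accepts a string label or an integer triple.
    """
    parts = _parse_ratio(ratio_label)
    g = math.gcd(math.gcd(parts[0], parts[1]), parts[2])
    parts = tuple(p // g for p in parts)
    rotations = [parts[i:] + parts[:i] for i in range(3)]
    best = min(rotations)
    return ":".join(str(p) for p in best)


def simplex_coords(triples, total: float | None = None) -> np.ndarray:
    """Barycentric triples -> 2-D Cartesian coordinates (unit triangle).

    The map is the standard ternary-plot projection
    x = (b + c/2) / s, y = (sqrt(3)/2) c / s for (a, b, c) with s = a+b+c;
    it is an isometry up to scale, so Euclidean structure in the simplex
    plane is preserved.
    """
    arr = np.atleast_2d(np.asarray(triples, dtype=float))
    s = arr.sum(axis=1) if total is None else float(total)
    a, b, c = arr[:, 0], arr[:, 1], arr[:, 2]
    x = (b + 0.5 * c) / s
    y = (math.sqrt(3.0) / 2.0) * c / s
    return np.column_stack([x, y])


def nearest_small_integer_ratio(triple, max_integer: int = 3,
                                min_fraction: float = 0.0) -> str:
    """Label of the small-integer-ratio point nearest an interval triple.

    Candidates are all gcd-reduced triples with entries in
    ``1..max_integer`` whose smallest normalized share is at least
    ``min_fraction`` (e.g. 0.15 for a 300 ms floor in a 2000 ms cycle).
    """
    arr = np.asarray(triple, dtype=float)
    frac = arr / arr.sum()
    best, best_d = None, np.inf
    for a in range(1, max_integer + 1):
        for b in range(1, max_integer + 1):
            for c in range(1, max_integer + 1):
                if math.gcd(math.gcd(a, b), c) != 1:
                    continue
                cand = np.array([a, b, c], dtype=float)
                cand /= cand.sum()
                if cand.min() < min_fraction:
                    continue
                d = float(((frac - cand) ** 2).sum())
                if d < best_d:
                    best, best_d = (a, b, c), d
    return ":".join(str(p) for p in best)
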