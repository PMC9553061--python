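"""Matplotlib helpers: filter trajectories and ternary (simplex) maps."""

from __future__ import annotations

import math

import numpy as np

from .rhythm_space import simplex_coords

__all__ = ["plot_trajectory", "plot_simplex_map", "plot_simplex_scatter"]


def plot_trajectory(results, ax=None, show_probs=True):
    """Plot posterior mean/variance over time with event markers.

    For pattern-inference results a second panel shows the template
    probabilities.  Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    traj = results.trajectory
    has_probs = show_probs and traj.template_probs is not None
    if ax is None:
        fig, axes = plt.subplots(2 if has_probs else 1, 1, sharex=True,
                                 figsize=(8, 5 if has_probs else 3))
        ax = axes[0] if has_probs else axes
    else:
        fig = ax.figure
        has_probs = False
    t = traj.times
    mu = traj.posterior_means
    sd = np.sqrt(traj.posterior_variances)
    ax.plot(t, mu, lw=1.0, label=r"$\mu_t$")
    ax.fill_between(t, mu - 2 * sd, mu + 2 * sd, alpha=0.25, lw=0)
    for ev in traj.event_times:
        ax.axvline(ev, color="k", lw=0.4, alpha=0.4)
    ax.plot(t, t, ls="--", lw=0.8, color="grey", label="nominal phase")
    ax.set_ylabel("phase (s)")
    ax.legend(loc="upper left", fontsize=8)
    if has_probs:
        ax2 = fig.axes[1]
        labels = traj.template_labels or []
        for m in range(traj.template_probs.shape[1]):
            lab = labels[m] if m < len(labels) else str(m)
            ax2.plot(t, traj.template_probs[:, m], lw=1.0, label=lab)
        ax2.set_ylabel(r"$p^m$")
        ax2.set_xlabel("time (s)")
        ax2.legend(loc="center right", fontsize=8)
    return fig


def _triangle_outline(ax, total, min_interval):
    verts = np.array([
        [total - 2 * min_interval, min_interval, min_interval],
        [min_interval, total - 2 * min_interval, min_interval],
        [min_interval, min_interval, total - 2 * min_interval],
        [total - 2 * min_interval, min_interval, min_interval],
    ])
    xy = simplex_coords(verts, total)
    ax.plot(xy[:, 0], xy[:, 1], color="k", lw=0.8)
    ax.set_aspect("equal")
    ax.axis("off")


def plot_simplex_map(triples, values, total=2000.0, min_interval=300.0,
                     ax=None, cmap="viridis", colorbar_label=""):
    """Scatter a per-rhythm scalar (e.g. entropy) over the simplex grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    xy = simplex_coords(np.asarray(triples, float), total)
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=np.asarray(values), s=6,
                    cmap=cmap, lw=0)
    _triangle_outline(ax, total, min_interval)
    cb = ax.figure.colorbar(sc, ax=ax, shrink=0.8)
    if colorbar_label:
        cb.set_label(colorbar_label)
    return ax.figure


def plot_simplex_scatter(triples, total=2000.0, min_interval=300.0,
                         ax=None, marks: dict | None = None, **kwargs):
    """Scatter raw simplex samples; ``marks`` adds labeled crosses
    (e.g. small-integer-ratio points)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    xy = simplex_coords(np.asarray(triples, float), total)
    kwargs.setdefault("s", 4)
    kwargs.setdefault("alpha", 0.5)
    ax.scatter(xy[:, 0], xy[:, 1], lw=0, **kwargs)
    if marks:
        mxy = simplex_coords(np.asarray(list(marks.values()), float), total)
        ax.scatter(mxy[:, 0], mxy[:, 1], marker="x", color="red", s=30)
        for (label, _), (x, y) in zip(marks.items(), mxy):
            ax.annotate(label, (x, y), fontsize=7,
                        xytext=(2, 2), textcoords="offset points")
    _triangle_outline(ax, total, min_interval)
    return ax.figure
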