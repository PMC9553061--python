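"""Simulation experiments and their summary statistics.

Three studies are orchestrated here:

1. Enculturated bias in two-interval tracking: models with and without a
   4:3 expectation template track 1:1, 4:3 and 2:1 rhythms; the bias shows
   up in first-interval phase corrections and pre-event uncertainty.
2. Categorization of the three-interval rhythm space: one-pass pattern
   inference over a corpus-derived bank, mapped as posterior entropy and
   the maximum-probability template per grid rhythm.
3. Iterated reproduction: pattern inference on the first repetition picks
   a template, single-template tracking of the remaining repetitions
   yields the reproduced rhythm, which seeds the next iteration.

Also here: Welch's t-test wrapper, a Gaussian KDE on the simplex
normalized against the uniform distribution, and a constrained mixture fit
(fixed component means at category centers, shared isotropic variance,
uniform background) with bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .domain import (MS, FilterConfig, StimulusSequence, TemplateBank,
                     load_defaults)
from .filters import PippetModel
from .pattern import PatternPippetModel
from .priors import restrict_bank
from .rhythm_space import (cyclic_class, enumerate_simplex,
                           nearest_small_integer_ratio, make_stimulus,
                           sample_uniform_rhythms, simplex_coords)

__all__ = ["run_experiment1", "run_experiment2", "run_experiment3",
           "kde_simplex", "category_weights", "compare_category_weights",
           "welch_t", "Experiment1Result", "Experiment3Result",
           "default_category_centers"]

log = logging.getLogger(__name__)


def welch_t(sample_a, sample_b) -> tuple:
    """Welch's two-sample t-test: returns (t, df, p).

    Uses the Welch statistic with Satterthwaite degrees of freedom and a
    two-sided p-value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Experiment 1: two-interval tracking with and without a 4:3 template
# ---------------------------------------------------------------------------

@dataclass
class Experiment1Result:
    """Tables from the two-interval tracking simulation."""

    phase_corrections: pd.DataFrame   # model, stimulus, run, cycle, correction
    pre_event_uncertainty: pd.DataFrame  # model, stimulus, run, mean_pre_V
    welch_tests: pd.DataFrame         # comparison, t, df, p

    def mean_first_interval_correction(self, model: str,
                                       stimulus: str) -> float:
        df = self.phase_corrections
        sel = df[(df["model"] == model) & (df["stimulus"] == stimulus)]
        return float(sel["correction"].mean())

    def mean_pre_event_uncertainty(self, model: str, stimulus: str) -> float:
        df = self.pre_event_uncertainty
        sel = df[(df["model"] == model) & (df["stimulus"] == stimulus)]
        return float(sel["mean_pre_V"].mean())

    def summary(self) -> str:
        lines = ["Two-interval tracking simulation", "=" * 54]
        for model in ("european", "malian"):
            for stim in ("1:1", "4:3", "2:1"):
                c = self.mean_first_interval_correction(model, stim)
                v = self.mean_pre_event_uncertainty(model, stim)
                lines.append(f"{model:9s} {stim:4s}  "
                             f"mean correction {c:+.5f} s   "
                             f"mean pre-event V {v:.6f}")
        lines.append("-" * 54)
        for _, row in self.welch_tests.iterrows():
            lines.append(f"{row['comparison']:34s} "
                         f"t({row['df']:.0f}) = {row['t']:+.2f}, "
                         f"p = {row['p']:.3g}")
        return "\n".join(lines)


def run_experiment1(config: FilterConfig | None = None, seed: int = 0,
                    repetitions: int | None = None,
                    runs_per_condition: int | None = None,
                    period_ms: float | None = None,
                    banks=None) -> Experiment1Result:
    """Two-interval rhythms (1:1, 4:3 as 58:42, 2:1) tracked by a model
    without (European) and with (Malian) a 4:3 expectation template.

    Per model x stimulus, ``runs_per_condition`` independent noisy runs of
    ``repetitions`` cycles are filtered.  Phase corrections after the first
    interval of each cycle, and the per-run mean pre-event uncertainty, are
    tabulated; Welch's t-tests compare uncertainty between stimuli within
    each model and between models per stimulus.
    """
    from .fixtures import experiment1_banks

    d1 = load_defaults()["experiment1"]
    repetitions = d1["repetitions"] if repetitions is None else repetitions
    runs_per_condition = d1["runs_per_condition"] \
        if runs_per_condition is None else runs_per_condition
    period_ms = d1["period_ms"] if period_ms is None else period_ms
    if config is None:
        config = FilterConfig.from_defaults()
    if banks is None:
        banks = dict(zip(("european", "malian"),
                         experiment1_banks(period_ms)))
    stimuli = {"1:1": (1, 1), "4:3": (58, 42), "2:1": (2, 1)}

    ss = np.random.SeedSequence(seed)
    corr_rows, unc_rows = [], []
    for mi, (model_name, bank) in enumerate(banks.items()):
        for si, (stim_name, ratio) in enumerate(stimuli.items()):
            frac = ratio[0] / (ratio[0] + ratio[1])
            intervals = (period_ms * frac, period_ms * (1.0 - frac))
            for run in range(runs_per_condition):
                child = np.random.SeedSequence(
                    entropy=ss.entropy, spawn_key=(mi, si, run))
                rng = np.random.default_rng(child)
                stim = make_stimulus(intervals, repetitions,
                                     event_noise=config.event_noise_scale,
                                     seed=rng)
                res = PatternPippetModel(
                    stim, bank, config,
                    tile_repetitions=repetitions).filter(rng=rng)
                # events alternate cycle-start / internal; corrections after
                # the first interval are at the internal (odd-index) events
                first_interval = res.phase_corrections[1::2]
                for cycle, c in enumerate(first_interval):
                    corr_rows.append({"model": model_name,
                                      "stimulus": stim_name,
                                      "run": run, "cycle": cycle,
                                      "correction": c})
                unc_rows.append({"model": model_name, "stimulus": stim_name,
                                 "run": run,
                                 "mean_pre_V":
                                     res.pre_event_variances.mean()})

    corr = pd.DataFrame(corr_rows)
    unc = pd.DataFrame(unc_rows)

    def sample(model, stim):
        sel = unc[(unc["model"] == model) & (unc["stimulus"] == stim)]
        return sel["mean_pre_V"].to_numpy()

    tests = []
    for model in banks:
        for a, b in (("1:1", "4:3"), ("1:1", "2:1"), ("4:3", "2:1")):
            t, df, p = welch_t(sample(model, a), sample(model, b))
            tests.append({"comparison": f"{model}: {a} vs {b}",
                          "t": t, "df": df, "p": p})
    if set(banks) == {"european", "malian"}:
        for stim in stimuli:
            t, df, p = welch_t(sample("european", stim),
                               sample("malian", stim))
            tests.append({"comparison": f"european vs malian: {stim}",
                          "t": t, "df": df, "p": p})
    return Experiment1Result(phase_corrections=corr,
                             pre_event_uncertainty=unc,
                             welch_tests=pd.DataFrame(tests))


# ---------------------------------------------------------------------------
# Experiment 2: categorization of the three-interval rhythm space
# ---------------------------------------------------------------------------

def run_experiment2(bank: TemplateBank, grid=None,
                    config: FilterConfig | None = None, seed: int = 0,
                    restrict_n: int | None = None) -> pd.DataFrame:
    """One-pass pattern inference over each rhythm of the simplex grid.

    For every grid triple the bank is restricted to the N nearest
    templates, the stimulus is presented once, and the final posterior over
    templates is summarized by its entropy (bits) and its maximum (the
    inferred pattern, also grouped by cyclic class).
    """
    d2 = load_defaults()["experiment2"]
    if grid is None:
        grid = enumerate_simplex(d2["total_ms"], d2["min_interval_ms"],
                                 d2["resolution_ms"])
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if config is None:
        config = FilterConfig.from_defaults()
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, triple in enumerate(grid):
        sub = restrict_bank(bank, triple, n=restrict_n)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=(i,)))
        stim = make_stimulus(triple, repetitions=1,
                             event_noise=config.event_noise_scale, seed=rng)
        res = PatternPippetModel(stim, sub, config,
                                 tile_repetitions=1).filter(rng=rng)
        label = res.map_template.label
        rows.append({"d1": triple[0], "d2": triple[1], "d3": triple[2],
                     "entropy": res.final_entropy,
                     "argmax_label": label,
                     "argmax_class": cyclic_class(label)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment 3: iterated reproduction
# ---------------------------------------------------------------------------

@dataclass
class Experiment3Result:
    """Records and summaries of the iterated-reproduction simulation."""

    records: pd.DataFrame        # trial, iteration, stimulus, label, reproduction
    initial_stimuli: np.ndarray  # (k, 3) uniform seeds of each trial
    final_triples: np.ndarray    # (k', 3) last-iteration reproductions
    excluded_trials: int = 0

    def summary(self) -> str:
        k = self.initial_stimuli.shape[0]
        lines = [
            "Iterated reproduction simulation",
            "=" * 44,
            f"trials:            {k} ({self.excluded_trials} excluded)",
            f"iterations:        {int(self.records['iteration'].max())}",
        ]
        if self.final_triples.size:
            labels = [nearest_small_integer_ratio(t, min_fraction=0.15)
                      for t in self.final_triples]
            counts = pd.Series([cyclic_class(l) for l in labels]) \
                .value_counts()
            top = ", ".join(f"{c}={n}" for c, n in counts.head(5).items())
            lines.append(f"nearest-ratio classes: {top}")
        return "\n".join(lines)


def _constant_param_view(bank: TemplateBank) -> TemplateBank:
    """Bank with strengths/variances held constant (pattern inference only)."""
    import dataclasses

    cfg = load_defaults()["bank"]
    templates = []
    for t in bank.templates:
        templates.append(dataclasses.replace(
            t,
            event_variances=np.full(t.n_events, cfg["constant_variance"]),
            event_strengths=np.full(t.n_events, cfg["constant_strength"])))
    return TemplateBank(templates=tuple(templates),
                        prior_probs=bank.prior_probs,
                        max_strength=bank.max_strength,
                        max_variance=bank.max_variance,
                        restriction_size=bank.restriction_size)


def run_experiment3(bank: TemplateBank, k_trials: int | None = None,
                    config: FilterConfig | None = None, seed: int = 0,
                    iterations: int | None = None,
                    repetitions: int | None = None,
                    total: float | None = None,
                    min_interval: float | None = None,
                    restrict_n: int | None = None,
                    initial_stimuli=None) -> Experiment3Result:
    """Iterated reproduction of uniformly sampled three-interval rhythms.

    Each trial starts from a uniform triple.  Per iteration: the stimulus
    (noisy onsets, ``repetitions`` cycles) is presented; pattern inference
    with constant strengths/variances on the first repetition picks the
    most plausible template; the prior-parameterized version of that
    template then tracks the full sequence, and each event of the next
    stimulus is placed at the mean, across cycles 2..R, of the updated
    posterior phase at that event.  Reproductions with a non-positive
    interval flag the trial as excluded.
    """
    d3 = load_defaults()["experiment3"]
    d2 = load_defaults()["experiment2"]
    k_trials = d3["trials"] if k_trials is None else k_trials
    iterations = d3["iterations"] if iterations is None else iterations
    repetitions = d3["repetitions"] if repetitions is None else repetitions
    total = d2["total_ms"] if total is None else total
    min_interval = d2["min_interval_ms"] if min_interval is None \
        else min_interval
    if config is None:
        config = FilterConfig.from_defaults()

    ss = np.random.SeedSequence(seed)
    if initial_stimuli is None:
        initial = sample_uniform_rhythms(
            k_trials, total, min_interval,
            seed=np.random.SeedSequence(entropy=ss.entropy, spawn_key=(0,)))
    else:
        initial = np.atleast_2d(np.asarray(initial_stimuli, dtype=float))
        k_trials = initial.shape[0]
    period_s = total * MS
    rows = []
    finals, excluded = [], 0
    for trial in range(k_trials):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=ss.entropy,
                                   spawn_key=(1, trial)))
        triple = initial[trial]
        alive = True
        for it in range(1, iterations + 1):
            stim = make_stimulus(triple, repetitions,
                                 event_noise=config.event_noise_scale,
                                 seed=rng)
            # stage 1: pattern inference on the first repetition only
            sub = restrict_bank(bank, triple, n=restrict_n)
            first_cycle = stim.event_times[stim.event_times
                                           <= period_s + config.dt]
            stim1 = StimulusSequence(
                nominal_intervals=np.asarray(triple, float),
                period=total, repetitions=1, event_times=first_cycle,
                includes_final_event=True)
            res1 = PatternPippetModel(
                stim1, _constant_param_view(sub), config,
                tile_repetitions=1).filter(rng=rng)
            template = sub.templates[res1.map_template_index]
            # stage 2: track all repetitions with the inferred template
            res2 = PippetModel(
                stim, template.tiled(repetitions),
                config).filter(rng=rng)
            post = res2.post_event_means()
            # events come 3 per cycle (+ closing onset); average the
            # within-cycle phase of each event over cycles 2..R
            per_cycle = post[:3 * repetitions].reshape(repetitions, 3)
            offsets = np.arange(repetitions)[:, None] * period_s
            rel = (per_cycle - offsets)[1:]
            rho = rel.mean(axis=0)
            d1 = rho[1] - rho[0]
            d2_ = rho[2] - rho[1]
            d3_ = period_s - (rho[2] - rho[0])
            reproduced = np.array([d1, d2_, d3_]) / MS
            if reproduced.min() <= 0:
                excluded += 1
                alive = False
                log.debug("trial %d excluded at iteration %d "
                          "(degenerate reproduction %s)", trial, it,
                          reproduced)
            else:
                reproduced *= total / reproduced.sum()
            rows.append({
                "trial": trial, "iteration": it,
                "stim_d1": triple[0], "stim_d2": triple[1],
                "stim_d3": triple[2], "template": template.label,
                "rep_d1": reproduced[0], "rep_d2": reproduced[1],
                "rep_d3": reproduced[2], "excluded": not alive})
            if not alive:
                break
            triple = reproduced
        if alive:
            finals.append(triple)
    return Experiment3Result(
        records=pd.DataFrame(rows), initial_stimuli=initial,
        final_triples=np.asarray(finals).reshape(-1, 3),
        excluded_trials=excluded)


# ---------------------------------------------------------------------------
# Density and category-weight summaries on the simplex
# ---------------------------------------------------------------------------

def _feasible_area(total: float, min_interval: float) -> float:
    """Area, in normalized simplex-plane coordinates, of the feasible set."""
    shrink = (total - 3.0 * min_interval) / total
    return (math.sqrt(3.0) / 4.0) * shrink ** 2


def kde_simplex(samples, bandwidth=None, grid=None,
                total: float | None = None,
                min_interval: float | None = None):
    """Gaussian KDE of simplex samples, normalized against uniform.

    The KDE is fit in 2-D simplex-plane coordinates (Silverman bandwidth by
    default) and evaluated on the grid; the returned ratio divides the
    density by the uniform density over the feasible region, so a
    structureless sample gives a ratio near 1 everywhere.

    Returns ``(grid, density, ratio)`` where ``density`` integrates to ~1
    over the plane.
    """
    d2 = load_defaults()["experiment2"]
    total = d2["total_ms"] if total is None else total
    min_interval = d2["min_interval_ms"] if min_interval is None \
        else min_interval
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 samples for a KDE")
    if grid is None:
        grid = enumerate_simplex(total, min_interval, d2["resolution_ms"])
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    kde = stats.gaussian_kde(simplex_coords(samples, total).T,
                             bw_method=bandwidth or "silverman")
    density = kde(simplex_coords(grid, total).T)
    uniform = 1.0 / _feasible_area(total, min_interval)
    return grid, density, density / uniform


def default_category_centers(total: float = 2000.0,
                             min_interval: float = 300.0,
                             max_integer: int = 3) -> dict:
    """Small-integer-ratio category centers feasible in the rhythm space.

    Returns ``{label: (d1, d2, d3)}`` for every gcd-reduced triple with
    entries up to ``max_integer`` whose scaled intervals respect the
    minimum duration.
    """
    centers = {}
    for a in range(1, max_integer + 1):
        for b in range(1, max_integer + 1):
            for c in range(1, max_integer + 1):
                if math.gcd(math.gcd(a, b), c) != 1:
                    continue
                s = a + b + c
                d = (total * a / s, total * b / s, total * c / s)
                if min(d) < min_interval:
                    continue
                centers[f"{a}:{b}:{c}"] = d
    return centers


def _fit_constrained_gmm(coords, centers_xy, sigma0=0.05,
                         max_iter=200, tol=1e-8, bg_density=1.0):
    """EM for a mixture with fixed means, shared isotropic variance and a
    uniform background component.  Returns (weights, bg_weight, sigma)."""
    n, _ = coords.shape
    k = centers_xy.shape[0]
    w = np.full(k, 0.9 / k)
    w_bg = 0.1
    sig2 = sigma0 ** 2
    d2 = ((coords[:, None, :] - centers_xy[None, :, :]) ** 2).sum(axis=2)
    prev = -np.inf
    for _ in range(max_iter):
        comp = w * np.exp(-0.5 * d2 / sig2) / (2.0 * np.pi * sig2)
        bg = w_bg * bg_density
        norm = comp.sum(axis=1) + bg
        ll = float(np.log(norm).sum())
        resp = comp / norm[:, None]
        resp_bg = bg / norm
        w = resp.sum(axis=0) / n
        w_bg = float(resp_bg.sum()) / n
        mass = resp.sum()
        if mass > 0:
            sig2 = float((resp * d2).sum()) / (2.0 * mass)
            sig2 = max(sig2, 1e-8)
        if abs(ll - prev) < tol * max(1.0, abs(ll)):
            break
        prev = ll
    else:
        log.warning("constrained mixture EM did not converge in %d "
                    "iterations", max_iter)
    return w, w_bg, math.sqrt(sig2)


def category_weights(samples, category_centers: dict | None = None,
                     total: float | None = None,
                     min_interval: float | None = None,
                     n_bootstrap: int | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Category weights of simplex samples via a constrained mixture fit.

    A Gaussian mixture with component means fixed at the category centers,
    one shared isotropic variance, and a uniform background component is
    fit by EM in simplex-plane coordinates; weights of cyclic permutations
    are grouped.  Bootstrap resampling of the samples (default N = 250)
    gives the SD of each grouped weight.

    Returns a DataFrame indexed by cyclic class with columns ``weight``
    and ``weight_sd``.
    """
    d2cfg = load_defaults()["experiment2"]
    mix = load_defaults()["mixture"]
    total = d2cfg["total_ms"] if total is None else total
    min_interval = d2cfg["min_interval_ms"] if min_interval is None \
        else min_interval
    n_bootstrap = mix["bootstrap"] if n_bootstrap is None else n_bootstrap
    if category_centers is None:
        category_centers = default_category_centers(total, min_interval)
    labels = list(category_centers)
    centers_xy = simplex_coords(
        np.asarray([category_centers[l] for l in labels]), total)
    coords = simplex_coords(np.atleast_2d(np.asarray(samples, float)), total)
    bg_density = 1.0 / _feasible_area(total, min_interval)
    classes = sorted({cyclic_class(l) for l in labels})
    member = np.zeros((len(classes), len(labels)))
    for j, lab in enumerate(labels):
        member[classes.index(cyclic_class(lab)), j] = 1.0

    def grouped(wts):
        return member @ wts

    w, w_bg, sigma = _fit_constrained_gmm(
        coords, centers_xy, max_iter=mix["max_iter"],
        tol=mix["tol"], bg_density=bg_density)
    point = grouped(w)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, len(classes)))
    for b in range(n_bootstrap):
        idx = rng.integers(0, coords.shape[0], coords.shape[0])
        wb, _, _ = _fit_constrained_gmm(
            coords[idx], centers_xy, max_iter=mix["max_iter"],
            tol=mix["tol"], bg_density=bg_density)
        boots[b] = grouped(wb)
    out = pd.DataFrame({"weight": point, "weight_sd": boots.std(axis=0)},
                       index=pd.Index(classes, name="cyclic_class"))
    out.attrs["background_weight"] = w_bg
    out.attrs["sigma"] = sigma
    return out


def compare_category_weights(samples_a, samples_b, **kwargs) -> pd.DataFrame:
    """Per-class weight difference (a - b) with a bootstrap z-test.

    p-values are two-sided normal approximations from the bootstrap SDs,
    Bonferroni-corrected across classes.
    """
    wa = category_weights(samples_a, **kwargs)
    wb = category_weights(samples_b, **kwargs)
    diff = wa["weight"] - wb["weight"]
    se = np.sqrt(wa["weight_sd"] ** 2 + wb["weight_sd"] ** 2)
    z = diff / se.replace(0.0, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = np.minimum(p * len(diff), 1.0)
    return pd.DataFrame({"weight_a": wa["weight"], "weight_b": wb["weight"],
                         "difference": diff, "se": se, "z": z,
                         "p_bonferroni": p_adj})
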