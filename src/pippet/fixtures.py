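"""Deterministic generators for all simulated-study inputs.

These generators define the study conditions: the hand-built two-interval
template banks for the enculturated-bias simulation, the pair of synthetic
metrical tables standing in for the corpus analyses of a strongly
stratified (German-folk-like) and a flatter (Turkish-makam-like) meter, and
planted mixture samples used as a known-truth oracle input for the
category-weight fit.  Every generator is a pure function of (params, seed).
"""

from __future__ import annotations

import numpy as np

from .domain import ExpectationTemplate, TemplateBank, load_defaults
from .priors import MetricalTable, synth_metrical_table
from .rhythm_space import simplex_coords

__all__ = ["experiment1_banks", "cultural_table_pair",
           "planted_mixture_samples"]


def experiment1_banks(period_ms: float | None = None, *,
                      strength: float | None = None,
                      variance_even: float | None = None,
                      variance_uneven: float | None = None,
                      background_rate: float | None = None):
    """The two-interval banks for the enculturated-bias simulation.

    Returns ``(european_bank, malian_bank)``: the first holds 1:1 and 2:1
    templates, the second adds a 4:3 template (realized as the 58:42 ratio
    measured in Malian drumming repertoire).  Priors are equiprobable; the
    1:1 template is more precise (smaller variance) than the uneven
    templates, which is what attracts uneven rhythms to the 2:1
    interpretation in the European model.
    """
    from .domain import make_two_interval_template

    d = load_defaults()
    tpl = d["templates"]
    period_ms = d["experiment1"]["period_ms"] if period_ms is None \
        else period_ms
    strength = tpl["strength"] if strength is None else strength
    variance_even = tpl["variance_even"] if variance_even is None \
        else variance_even
    variance_uneven = tpl["variance_uneven"] if variance_uneven is None \
        else variance_uneven
    background_rate = tpl["background_rate"] if background_rate is None \
        else background_rate

    def two(ratio, variance, label):
        return make_two_interval_template(
            ratio, period_ms, strength=strength, variance=variance,
            background_rate=background_rate, label=label)

    even = two((1, 1), variance_even, "1:1")
    uneven = two((2, 1), variance_uneven, "2:1")
    malian43 = two((58, 42), variance_uneven, "4:3")
    bank_kwargs = dict(max_strength=strength, max_variance=variance_uneven)
    european = TemplateBank(templates=(even, uneven),
                            prior_probs=np.array([0.5, 0.5]), **bank_kwargs)
    malian = TemplateBank(templates=(even, uneven, malian43),
                          prior_probs=np.full(3, 1.0 / 3.0), **bank_kwargs)
    return european, malian


def cultural_table_pair(seed=0) -> tuple:
    """A (hierarchical, flattened) pair of synthetic metrical tables.

    Both cover the meters 2/4, 4/4 (binary simple), 6/8 (binary compound)
    and 3/4 (ternary simple) at 16th-note resolution (periods 8, 16, 12,
    12).  The hierarchical table concentrates onset probability on strong
    metrical positions; the flattened one keeps the same hierarchy at a
    lower concentration, emulating a less stratified meter.  Template banks
    built from the flattened table have higher prior entropy.
    """
    cfg = load_defaults()["fixtures"]
    ss = np.random.SeedSequence(seed).spawn(2)
    hierarchical = synth_metrical_table(
        "hierarchical", concentration=cfg["hierarchical_concentration"],
        seed=ss[0], label="hierarchical")
    flattened = synth_metrical_table(
        "hierarchical", concentration=cfg["flattened_concentration"],
        seed=ss[1], label="flattened")
    return hierarchical, flattened


def planted_mixture_samples(weights, centers, sd: float, n: int, seed=None,
                            total: float = 2000.0,
                            min_interval: float = 300.0) -> np.ndarray:
    """Simplex samples from a known mixture over interval-triple centers.

    ``centers`` are interval triples (ms) summing to ``total``; ``sd`` is
    the isotropic SD (ms) of the in-plane Gaussian scatter around each
    center.  Samples violating the minimum-interval constraint are
    rejected and redrawn, so empirical class frequencies track ``weights``
    up to the (small) differential rejection mass.  Returns an (n, 3)
    array of triples summing to ``total``.
    """
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] != weights.size:
        raise ValueError("one center per weight required")
    rng = np.random.default_rng(seed)
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        k = n - filled
        comp = rng.choice(weights.size, size=k, p=weights)
        # isotropic scatter in the simplex plane: draw in 3-space and
        # project onto the zero-sum subspace (the projection of an
        # isotropic Gaussian is isotropic in-plane)
        z = rng.standard_normal((k, 3)) * sd
        z -= z.mean(axis=1, keepdims=True)
        cand = centers[comp] + z
        ok = cand.min(axis=1) >= min_interval
        n_ok = int(ok.sum())
        out[filled:filled + n_ok] = cand[ok]
        filled += n_ok
    # renormalize away accumulated rounding so rows sum to `total` exactly
    out *= total / out.sum(axis=1, keepdims=True)
    return out
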