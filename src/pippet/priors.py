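"""Corpus-derived priors: metrical onset-probability tables -> template banks.

A metrical table gives, for each meter (time signature), the probability
that an onset falls at each metrical position on a 16th-note grid.  Every
strictly increasing triple of positions within a meter's cycle defines a
three-interval pattern (the third interval closes the cycle back to the
first position), which reduces to a pair of consecutive-interval ratios
<r1, r2>.  The probability of a ratio pattern is the product of its onset
probabilities, summed over all realizations in a meter, averaged across
meters and normalized over the pattern set.  Each surviving pattern becomes
an expectation template whose prior p0^m sets its strength
(lambda^m = p0^m lambda_max) and variance (v^m = (1 - p0^m) v_max):
patterns frequent in the corpus get strong, precise expectations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .domain import MS, ExpectationTemplate, TemplateBank, load_defaults

__all__ = ["MetricalTable", "RatioPattern", "enumerate_patterns",
           "pattern_probability", "ratio_pattern_distribution",
           "ratios_to_intervals", "build_bank", "restrict_bank",
           "synth_metrical_table", "METER_PERIODS"]

log = logging.getLogger(__name__)

# Period in 16th-note positions of the supported time signatures.
METER_PERIODS = {"2/4": 8, "4/4": 16, "6/8": 12, "3/4": 12}


@dataclass(frozen=True)
class MetricalTable:
    """Per-meter categorical distributions of onset position.

    ``onset_probs[meter]`` is a length-N_M array, P(n | M) for positions
    n = 0..N_M-1.  ``label`` names the table (e.g. a corpus or profile).
    """

    onset_probs: dict
    label: str = ""

    def __post_init__(self):
        probs = {m: np.asarray(p, dtype=float)
                 for m, p in self.onset_probs.items()}
        for m, p in probs.items():
            if np.any(p < 0):
                raise ValueError(f"negative onset probability in meter {m}")
        object.__setattr__(self, "onset_probs", probs)

    @property
    def meters(self) -> list:
        return list(self.onset_probs)

    def period(self, meter: str) -> int:
        return self.onset_probs[meter].size

    def to_csv(self, path) -> None:
        rows = [
            {"meter": m, "label": self.label, "position": n,
             "probability": p[n]}
            for m, p in self.onset_probs.items() for n in range(p.size)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MetricalTable":
        df = pd.read_csv(path)
        probs = {}
        for meter, grp in df.groupby("meter", sort=False):
            grp = grp.sort_values("position")
            probs[str(meter)] = grp["probability"].to_numpy()
        label = str(df["label"].iloc[0]) if "label" in df else ""
        return cls(onset_probs=probs, label=label)


@dataclass(frozen=True)
class RatioPattern:
    """A pair of consecutive-interval ratios with its probability.

    ``intervals`` is the gcd-reduced integer triple (a, b, c) realizing the
    ratios r1 = a/b, r2 = b/c.
    """

    r1: Fraction
    r2: Fraction
    prob: float
    intervals: tuple

    @property
    def label(self) -> str:
        a, b, c = self.intervals
        return f"{a}:{b}:{c}"


def _triple_intervals(triple, period: int) -> tuple:
    """Interval triple of a position triple, closing the cycle (wrap)."""
    ni, nj, nk = triple
    return (nj - ni, nk - nj, period - (nk - ni))


def _reduce(intervals) -> tuple:
    a, b, c = intervals
    g = math.gcd(math.gcd(a, b), c)
    return (a // g, b // g, c // g)


def enumerate_patterns(table: MetricalTable) -> list:
    """All strictly increasing position triples per meter.

    Returns ``[(meter, (n_i, n_j, n_k)), ...]`` over positions with defined
    (possibly zero) probability; meters with fewer than 3 positions are
    skipped with a warning.
    """
    out = []
    for meter in table.meters:
        n_pos = table.period(meter)
        if n_pos < 3:
            log.warning("meter %s has fewer than 3 positions; skipped", meter)
            continue
        for triple in itertools.combinations(range(n_pos), 3):
            out.append((meter, triple))
    return out


def ratio_pattern_distribution(table: MetricalTable) -> list:
    """The normalized distribution over deduplicated ratio patterns.

    Per meter M, P(<r1,r2> | M) sums the onset-probability products over
    all position triples realizing the pattern; meters are averaged with
    weight 1/|M| and the result normalized over the final pattern set.
    Patterns are deduplicated by their gcd-reduced interval triple.
    Returns RatioPatterns sorted by decreasing probability.
    """
    n_meters = len(table.meters)
    mass: dict = {}
    for meter, triple in enumerate_patterns(table):
        probs = table.onset_probs[meter]
        w = probs[triple[0]] * probs[triple[1]] * probs[triple[2]]
        if w == 0.0:
            continue
        key = _reduce(_triple_intervals(triple, table.period(meter)))
        mass[key] = mass.get(key, 0.0) + w / n_meters
    total = sum(mass.values())
    if total == 0:
        return []
    patterns = [
        RatioPattern(r1=Fraction(a, b), r2=Fraction(b, c), prob=w / total,
                     intervals=(a, b, c))
        for (a, b, c), w in mass.items()
    ]
    patterns.sort(key=lambda p: (-p.prob, p.intervals))
    return patterns


def pattern_probability(table: MetricalTable, ratio_pattern) -> float:
    """Probability of one ratio pattern under the table's distribution.

    ``ratio_pattern`` may be a RatioPattern, an (r1, r2) pair or an
    interval triple; unreachable patterns have probability 0.
    """
    if isinstance(ratio_pattern, RatioPattern):
        key = _reduce(ratio_pattern.intervals)
    elif len(ratio_pattern) == 3:
        key = _reduce(tuple(int(x) for x in ratio_pattern))
    else:
        r1 = Fraction(ratio_pattern[0]).limit_denominator(10**6)
        r2 = Fraction(ratio_pattern[1]).limit_denominator(10**6)
        a = r1.numerator * r2.numerator
        b = r1.denominator * r2.numerator
        c = r1.denominator * r2.denominator
        key = _reduce((a, b, c))
    for p in ratio_pattern_distribution(table):
        if _reduce(p.intervals) == key:
            return p.prob
    return 0.0


def ratios_to_intervals(r1: float, r2: float, total_duration: float) -> tuple:
    """Interval durations (d1, d2, d3) with d1/d2 = r1, d2/d3 = r2 and
    d1 + d2 + d3 = ``total_duration``."""
    if r1 <= 0 or r2 <= 0 or total_duration <= 0:
        raise ValueError("ratios and total duration must be positive")
    r1, r2 = float(r1), float(r2)
    d3 = total_duration / (r1 * r2 + r2 + 1.0)
    d2 = r2 * d3
    d1 = r1 * d2
    return (d1, d2, d3)


def build_bank(table: MetricalTable, total_duration: float = 2000.0,
               min_interval: float = 300.0,
               max_strength: float | None = None,
               max_variance: float | None = None,
               constant_params: bool = False,
               background_rate: float | None = None,
               restriction_size: int | None = None) -> TemplateBank:
    """Template bank from a metrical table for a given rhythm space.

    Durations in ms.  Ratio patterns whose realized intervals violate the
    rhythm space's minimum interval are dropped and the priors
    renormalized.  With ``constant_params`` the prior-dependent
    parameterization is replaced by shared constant strengths/variances
    (the pattern-inference-only configuration).
    """
    if 3 * min_interval > total_duration:
        raise ValueError("3 * min_interval must not exceed total duration")
    defaults = load_defaults()
    bank_cfg = defaults["bank"]
    max_strength = bank_cfg["max_strength"] if max_strength is None \
        else max_strength
    max_variance = bank_cfg["max_variance"] if max_variance is None \
        else max_variance
    background_rate = defaults["templates"]["background_rate"] \
        if background_rate is None else background_rate
    restriction_size = bank_cfg["restriction_size"] \
        if restriction_size is None else restriction_size

    kept, priors = [], []
    for pat in ratio_pattern_distribution(table):
        d = ratios_to_intervals(float(pat.r1), float(pat.r2), total_duration)
        if min(d) < min_interval - 1e-9:
            continue
        kept.append((pat, d))
        priors.append(pat.prob)
    if not kept:
        raise ValueError("no patterns survive the duration filter")
    p0 = np.asarray(priors) / np.sum(priors)

    templates = []
    for (pat, d), p in zip(kept, p0):
        if constant_params:
            strength = bank_cfg["constant_strength"]
            variance = bank_cfg["constant_variance"]
        else:
            strength = p * max_strength
            # floor keeps the degenerate p0 = 1 case a valid template
            variance = max((1.0 - p) * max_variance, 1e-6)
        phases = np.array([0.0, d[0], d[0] + d[1]]) * MS
        templates.append(ExpectationTemplate(
            event_phases=phases,
            event_variances=np.full(3, variance),
            event_strengths=np.full(3, strength),
            background_rate=background_rate,
            cycle_period=total_duration * MS,
            label=pat.label,
        ))
    return TemplateBank(templates=tuple(templates), prior_probs=p0,
                        max_strength=max_strength, max_variance=max_variance,
                        restriction_size=restriction_size)


def restrict_bank(bank: TemplateBank, stimulus_intervals,
                  n: int | None = None) -> TemplateBank:
    """Keep the N templates nearest the stimulus and renormalize priors.

    Distance is Euclidean between interval vectors in ms.  If the bank has
    at most N templates it is returned unchanged.
    """
    n = bank.restriction_size if n is None else n
    if len(bank) <= n:
        return bank
    target = np.asarray(stimulus_intervals, dtype=float)
    d2 = ((bank.interval_vectors() - target) ** 2).sum(axis=1)
    keep = np.sort(np.argsort(d2, kind="stable")[:n])
    priors = bank.prior_probs[keep]
    return TemplateBank(
        templates=tuple(bank.templates[i] for i in keep),
        prior_probs=priors / priors.sum(),
        max_strength=bank.max_strength, max_variance=bank.max_variance,
        restriction_size=bank.restriction_size)


def _metrical_depths(meter: str, n_pos: int) -> np.ndarray:
    """Metrical-level depth of each 16th-note position (0 = downbeat)."""
    depths = np.full(n_pos, 3, dtype=int)
    if meter == "2/4":            # 8 positions, binary simple
        levels = [[0], [4], [2, 6]]
    elif meter == "4/4":          # 16 positions, binary simple
        levels = [[0], [8], [4, 12], [2, 6, 10, 14]]
        depths[:] = 4
    elif meter == "6/8":          # 12 positions, binary compound
        levels = [[0], [6], [2, 4, 8, 10]]
    elif meter == "3/4":          # 12 positions, ternary simple
        levels = [[0], [4, 8], [2, 6, 10]]
    else:
        raise ValueError(f"no metrical hierarchy defined for meter {meter}")
    for depth, positions in enumerate(levels):
        depths[positions] = depth
    return depths


def synth_metrical_table(profile: str = "hierarchical", meters=None,
                         concentration: float = 1.0, seed=None,
                         jitter: float | None = None,
                         label: str | None = None) -> MetricalTable:
    """Synthetic metrical onset-probability table.

    ``hierarchical`` assigns onset probability decreasing with
    metrical-level depth, P(n) proportional to exp(-concentration * depth),
    times a small seeded multiplicative jitter bounded so that the
    between-level ordering is preserved; ``flat`` is exactly uniform per
    meter.  Deterministic given (params, seed).
    """
    if meters is None:
        meters = dict(METER_PERIODS)
    if jitter is None:
        jitter = load_defaults()["fixtures"]["jitter"]
    if profile not in ("flat", "hierarchical"):
        raise ValueError("profile must be 'flat' or 'hierarchical'")
    rng = np.random.default_rng(seed)
    probs = {}
    for meter, n_pos in meters.items():
        if profile == "flat":
            p = np.full(n_pos, 1.0 / n_pos)
        else:
            depths = _metrical_depths(meter, n_pos)
            w = np.exp(-concentration * depths)
            w *= 1.0 + jitter * (2.0 * rng.random(n_pos) - 1.0)
            p = w / w.sum()
        probs[meter] = p
    if label is None:
        label = f"{profile}(c={concentration:g},seed={seed})"
    return MetricalTable(onset_probs=probs, label=label)
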