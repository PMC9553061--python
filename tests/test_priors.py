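"""Metrical tables, ratio-pattern distributions and bank construction."""

import itertools
import math

import numpy as np
import pytest

from pippet.pattern import posterior_entropy
from pippet.priors import (MetricalTable, build_bank, enumerate_patterns,
                           pattern_probability, ratio_pattern_distribution,
                           ratios_to_intervals, restrict_bank,
                           synth_metrical_table)


def _uniform_table(n_pos=8, meter="2/4"):
    return MetricalTable(onset_probs={meter: np.full(n_pos, 1.0 / n_pos)},
                         label="uniform")


class TestEnumeratePatterns:
    def test_counts_follow_combinatorics(self):
        table = MetricalTable(onset_probs={"m": np.full(4, 0.25)})
        assert len(enumerate_patterns(table)) == 4        # C(4,3)
        assert len(enumerate_patterns(_uniform_table(8))) == 56  # C(8,3)

    def test_short_meter_skipped_with_warning(self, caplog):
        table = MetricalTable(onset_probs={"m": np.full(2, 0.5)})
        with caplog.at_level("WARNING"):
            assert enumerate_patterns(table) == []
        assert "fewer than 3" in caplog.text

    def test_wrap_closure_interval_arithmetic(self):
        # triple (0, 2, 4) in an 8-position meter: intervals (2, 2, 4),
        # i.e. the reduced pattern 1:1:2 with ratios r1 = 1, r2 = 1/2
        patterns = ratio_pattern_distribution(_uniform_table(8))
        labels = {p.label for p in patterns}
        assert "1:1:2" in labels
        p112 = next(p for p in patterns if p.label == "1:1:2")
        assert (float(p112.r1), float(p112.r2)) == (1.0, 0.5)


class TestPatternProbability:
    def test_multiplicity_under_uniform_onsets(self):
        # with uniform onset probabilities every triple has equal weight,
        # so pattern probability is proportional to realization count
        table = _uniform_table(8)
        counts = {}
        for ni, nj, nk in itertools.combinations(range(8), 3):
            a, b, c = nj - ni, nk - nj, 8 - (nk - ni)
            g = math.gcd(math.gcd(a, b), c)
            key = (a // g, b // g, c // g)
            counts[key] = counts.get(key, 0) + 1
        total = sum(counts.values())
        for key, n in counts.items():
            assert pattern_probability(table, key) == pytest.approx(
                n / total, abs=1e-12)

    def test_zero_probability_position_kills_patterns(self):
        probs = np.full(8, 1.0 / 8)
        probs[3] = 0.0
        table = MetricalTable(onset_probs={"m": probs})
        # (0, 3, 6) has intervals (3, 3, 2); all realizations of 3:3:2 in
        # an 8-position meter pass through position 3 or use it
        for p in ratio_pattern_distribution(table):
            assert p.prob > 0
        # triple containing position 3 contributes nothing: probability of
        # the whole set still sums to 1
        total = sum(p.prob for p in ratio_pattern_distribution(table))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_meters_match_single_meter(self):
        one = _uniform_table(8)
        two = MetricalTable(onset_probs={"a": np.full(8, 1 / 8),
                                         "b": np.full(8, 1 / 8)})
        da = {p.label: p.prob for p in ratio_pattern_distribution(one)}
        db = {p.label: p.prob for p in ratio_pattern_distribution(two)}
        assert da.keys() == db.keys()
        for k in da:
            assert da[k] == pytest.approx(db[k], abs=1e-12)

    def test_distribution_sums_to_one(self, table_pair):
        for table in table_pair:
            total = sum(p.prob for p in ratio_pattern_distribution(table))
            assert total == pytest.approx(1.0, abs=1e-9)


class TestRatiosToIntervals:
    def test_isochrony(self):
        d = ratios_to_intervals(1.0, 1.0, 2000.0)
        assert d == pytest.approx((2000 / 3,) * 3)

    def test_pattern_1_1_2(self):
        # 1:1:2 pattern: r1 = 1, r2 = 1/2
        d = ratios_to_intervals(1.0, 0.5, 2000.0)
        assert d == pytest.approx((500.0, 500.0, 1000.0), abs=1e-9)

    def test_round_trip(self, rng):
        for _ in range(50):
            r1, r2 = rng.uniform(0.2, 5.0, 2)
            d1, d2, d3 = ratios_to_intervals(r1, r2, 2000.0)
            assert d1 + d2 + d3 == pytest.approx(2000.0, abs=1e-9)
            assert d1 / d2 == pytest.approx(r1, abs=1e-9)
            assert d2 / d3 == pytest.approx(r2, abs=1e-9)


class TestBuildBank:
    def test_uniform_table_contains_simple_patterns(self):
        bank = build_bank(_uniform_table(8), 2000.0, 300.0)
        labels = set(bank.labels)
        assert {"1:1:2", "1:2:1", "2:1:1"} <= labels
        # most-realized patterns get the largest priors
        top = bank.labels[int(np.argmax(bank.prior_probs))]
        dist = {p.label: p.prob
                for p in ratio_pattern_distribution(_uniform_table(8))}
        kept = {l: dist[l] for l in bank.labels}
        assert kept[top] == max(kept.values())

    def test_concentrated_table_favors_simple_ratios(self, table_pair):
        # onset mass on strong beats gives higher priors to patterns of
        # small integers than to complex ones
        bank = build_bank(table_pair[0])
        p = dict(zip(bank.labels, bank.prior_probs))
        simple = max(p.get("1:1:1", 0.0), p.get("1:1:2", 0.0))
        complex_patterns = [v for l, v in p.items()
                            if max(int(x) for x in l.split(":")) >= 5]
        assert complex_patterns
        assert simple > max(complex_patterns)

    def test_min_interval_filter_and_prior_renormalization(self):
        bank = build_bank(_uniform_table(8), 2000.0, 300.0)
        assert np.all(bank.interval_vectors() >= 300.0 - 1e-9)
        assert bank.prior_probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_probability_pattern_excluded(self):
        probs = np.zeros(8)
        probs[[0, 2, 4]] = 1.0 / 3
        table = MetricalTable(onset_probs={"m": probs})
        bank = build_bank(table, 2000.0, 300.0)
        # the only position triple is (0, 2, 4): intervals (2, 2, 4)
        assert bank.labels == ["1:1:2"]

    def test_parameterization_from_priors(self, hier_bank):
        p0 = hier_bank.prior_probs
        for template, p in zip(hier_bank.templates, p0):
            assert template.event_strengths[0] == pytest.approx(
                p * hier_bank.max_strength)
            assert template.event_variances[0] == pytest.approx(
                (1.0 - p) * hier_bank.max_variance)

    def test_constant_parameterization_flag(self, table_pair):
        bank = build_bank(table_pair[0], constant_params=True)
        strengths = {t.event_strengths[0] for t in bank.templates}
        variances = {t.event_variances[0] for t in bank.templates}
        assert len(strengths) == 1 and len(variances) == 1

    def test_meter_order_invariance(self, table_pair):
        hier = table_pair[0]
        reversed_table = MetricalTable(
            onset_probs=dict(reversed(list(hier.onset_probs.items()))),
            label=hier.label)
        a = build_bank(hier)
        b = build_bank(reversed_table)
        assert set(a.labels) == set(b.labels)
        pa = dict(zip(a.labels, a.prior_probs))
        pb = dict(zip(b.labels, b.prior_probs))
        for k in pa:
            assert pa[k] == pytest.approx(pb[k], abs=1e-12)


class TestRestrictBank:
    def test_restriction_size_and_renormalization(self, hier_bank):
        sub = restrict_bank(hier_bank, (666.7, 666.7, 666.7), n=22)
        assert len(sub) == 22
        assert sub.prior_probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exact_match_always_retained(self, hier_bank):
        for i in (0, len(hier_bank) // 2, len(hier_bank) - 1):
            target = hier_bank.interval_vectors()[i]
            sub = restrict_bank(hier_bank, target, n=5)
            assert hier_bank.labels[i] in sub.labels

    def test_large_n_returns_bank_unchanged(self, hier_bank):
        sub = restrict_bank(hier_bank, (500.0, 500.0, 1000.0),
                            n=len(hier_bank) + 10)
        assert sub is hier_bank


class TestSynthMetricalTable:
    def test_flat_profile_is_uniform(self):
        table = synth_metrical_table("flat", seed=1)
        for meter, p in table.onset_probs.items():
            np.testing.assert_allclose(p, 1.0 / p.size, atol=1e-12)

    def test_high_concentration_concentrates_on_downbeat(self):
        table = synth_metrical_table("hierarchical", concentration=50.0,
                                     seed=0, jitter=0.0)
        for meter, p in table.onset_probs.items():
            assert p[0] > 0.99

    def test_seeds_differ_but_level_ordering_preserved(self):
        from pippet.priors import _metrical_depths

        a = synth_metrical_table("hierarchical", concentration=1.0, seed=1)
        b = synth_metrical_table("hierarchical", concentration=1.0, seed=2)
        assert any(not np.allclose(a.onset_probs[m], b.onset_probs[m])
                   for m in a.meters)
        for table in (a, b):
            for meter, p in table.onset_probs.items():
                depths = _metrical_depths(meter, p.size)
                # every shallower-level position outweighs every deeper one
                for d in range(depths.max()):
                    assert p[depths == d].min() > p[depths > d].max()

    def test_flatter_table_gives_higher_prior_entropy(self, hier_bank,
                                                      flat_bank):
        assert posterior_entropy(flat_bank.prior_probs) > \
            posterior_entropy(hier_bank.prior_probs)

    def test_table_csv_round_trip(self, table_pair, tmp_path):
        table = table_pair[0]
        path = tmp_path / "table.csv"
        table.to_csv(path)
        loaded = MetricalTable.from_csv(path)
        assert loaded.meters == table.meters
        for m in table.meters:
            np.testing.assert_allclose(loaded.onset_probs[m],
                                       table.onset_probs[m], atol=1e-15)
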