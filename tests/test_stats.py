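"""Survival statistics: KM oracle equivalence, FH tests, MaxCombo, similarity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from tkisim.fixtures import event_times_fixture
from tkisim.stats import (
    ComparisonReport,
    bootstrap_similarity,
    effect_model,
    km_estimate,
    km_median,
    maxcombo,
    weighted_logrank,
)

from conftest import brute_force_km, brute_force_logrank_score


def table(times, events, groups):
    return pd.DataFrame({"time": times, "event": events, "group": groups})


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        t = table([1, 2, 3], [0, 0, 0], ["x"] * 3)
        curve = km_estimate(t)
        assert len(curve.times) == 0 or np.all(curve.survival == 1.0)
        assert curve.evaluate(10.0) == 1.0

    def test_two_events_by_hand(self):
        t = table([1.0, 2.0], [1, 1], ["x", "x"])
        curve = km_estimate(t)
        assert curve.evaluate(1.5) == pytest.approx(0.5)
        assert curve.evaluate(2.5) == pytest.approx(0.0)

    def test_single_subject_step(self):
        t = table([5.0], [1], ["x"])
        curve = km_estimate(t)
        assert curve.evaluate(4.999) == 1.0
        assert curve.evaluate(5.0) == 0.0

    def test_matches_brute_force_on_all_small_tables(self):
        # every event/censor pattern on tables of up to 4 subjects
        times = [1.0, 2.0, 3.0, 4.0]
        for n in (1, 2, 3, 4):
            for pattern in itertools.product([0, 1], repeat=n):
                if not any(pattern):
                    continue
                t = table(times[:n], list(pattern), ["x"] * n)
                curve = km_estimate(t)
                et, surv = brute_force_km(times[:n], pattern)
                assert np.allclose(curve.times, et)
                assert np.allclose(curve.survival, surv)

    def test_censoring_after_last_event_irrelevant(self):
        base = table([1.0, 2.0, 3.0], [1, 1, 0], ["x"] * 3)
        extended = table([1.0, 2.0, 3.0, 9.0], [1, 1, 0, 0], ["x"] * 4)
        # risk sets at the event times gain one subject; compare the curves
        # where the extra late censoring cannot matter: after the last event
        c1, c2 = km_estimate(base), km_estimate(extended)
        assert c1.evaluate(100.0) > 0  # censoring-terminated curve stays up
        t = table([1.0, 2.0], [1, 1], ["x"] * 2)
        t_ext = table([1.0, 2.0, 50.0], [1, 1, 0], ["x", "x", "x"])
        assert km_estimate(t_ext).evaluate(2.5) == pytest.approx(1 / 3)

    def test_greenwood_variance_closed_form(self):
        # n=3, events at 1 and 2: var(S(2)) by direct Greenwood evaluation
        t = table([1.0, 2.0, 3.0], [1, 1, 0], ["x"] * 3)
        curve = km_estimate(t)
        s2 = (2 / 3) * (1 / 2)
        greenwood = s2**2 * (1 / (3 * 2) + 1 / (2 * 1))
        assert curve.variance[-1] == pytest.approx(greenwood)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(table([-1.0], [1], ["x"]))

    def test_median(self):
        t = table([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], ["x"] * 4)
        assert km_median(t) == 2.0
        t2 = table([1.0, 2.0], [0, 0], ["x"] * 2)
        assert km_median(t2) == np.inf


class TestWeightedLogrank:
    def test_identical_groups_statistic_zero(self):
        t = table([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0], list("aaabbb"))
        result = weighted_logrank(t)
        assert result["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_standard_logrank_matches_brute_force(self, toy_event_table):
        result = weighted_logrank(toy_event_table, 0.0, 0.0)
        u, var = brute_force_logrank_score(
            toy_event_table["time"],
            toy_event_table["event"],
            toy_event_table["group"] == "b",
        )
        assert result["score"] == pytest.approx(u, rel=1e-12)
        assert result["statistic"] == pytest.approx(u / np.sqrt(var), rel=1e-12)

    def test_standard_logrank_matches_lifelines(self):
        rng = np.random.default_rng(0)
        t = table(
            np.concatenate([rng.exponential(10, 40), rng.exponential(6, 40)]),
            np.concatenate([rng.random(40) < 0.8, rng.random(40) < 0.8]),
            ["a"] * 40 + ["b"] * 40,
        )
        ours = weighted_logrank(t, 0.0, 0.0)
        ll = logrank_test(
            t[t.group == "a"]["time"], t[t.group == "b"]["time"],
            t[t.group == "a"]["event"], t[t.group == "b"]["event"],
        )
        assert ours["statistic"] ** 2 == pytest.approx(ll.test_statistic, rel=1e-6)
        assert ours["p"] == pytest.approx(ll.p_value, rel=1e-6)

    def test_permutation_matches_exhaustive_enumeration(self):
        # n = 8, 4 per group: all 70 assignments enumerable; the permutation
        # p-value must equal the exhaustive tail probability of |Z|
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        groups = list("aaaabbbb")
        t = table(times, events, groups)
        result = weighted_logrank(t, 0.0, 0.0, method="permutation",
                                  n_permutations=10_000)
        observed = abs(result["statistic"])
        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(combo)] = True
            u, var = brute_force_logrank_score(times, events, mask)
            z = abs(u / np.sqrt(var)) if var > 0 else 0.0
            count += z >= observed - 1e-12
            total += 1
        assert result["p"] == pytest.approx(count / total, abs=1e-12)

    def test_fh_weights_change_emphasis(self):
        # late-separation data: the late-weighted test is more extreme
        t = table(
            [1, 2, 3, 10, 11, 12, 1.5, 2.5, 3.5, 20, 21, 22],
            [1] * 12,
            ["a"] * 6 + ["b"] * 6,
        )
        early = abs(weighted_logrank(t, 1.0, 0.0)["statistic"])
        late = abs(weighted_logrank(t, 0.0, 1.0)["statistic"])
        assert late != early

    def test_one_group_rejected(self):
        t = table([1, 2], [1, 1], ["a", "a"])
        with pytest.raises(ValueError):
            weighted_logrank(t)


class TestMaxCombo:
    def test_identical_groups_p_near_one(self):
        t = table([1, 2, 3, 4, 1, 2, 3, 4], [1, 1, 1, 0] * 2, list("aaaabbbb"))
        result = maxcombo(t, method="permutation", n_permutations=500, seed=1)
        assert result["p"] > 0.9

    def test_single_weight_reduces_to_weighted_logrank(self, toy_event_table):
        single = maxcombo(toy_event_table, weight_set=((0.0, 0.0),), method="mvn")
        base = weighted_logrank(toy_event_table, 0.0, 0.0)
        assert single["statistic"] == pytest.approx(abs(base["statistic"]))
        assert single["p"] == pytest.approx(base["p"], rel=1e-2)

    def test_statistic_is_max_of_components(self, toy_event_table):
        result = maxcombo(toy_event_table, method="mvn")
        components = [v for k, v in result.items() if k.startswith("z_")]
        assert result["statistic"] == pytest.approx(max(abs(c) for c in components))

    def test_permutation_matches_exhaustive_enumeration_small_table(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 0, 1]
        t = table(times, events, list("aaabbb"))
        result = maxcombo(t, method="permutation", n_permutations=10_000, seed=0)
        # exhaustive: 20 assignments of 3 vs 3
        from tkisim.stats import _fh_components, _standardized, DEFAULT_WEIGHT_SET

        observed = result["statistic"]
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(combo)] = True
            scores, cov = _fh_components(
                np.array(times), np.array(events, bool), mask,
                list(DEFAULT_WEIGHT_SET),
            )
            stat = np.max(np.abs(_standardized(scores, cov)))
            count += stat >= observed - 1e-12
            total += 1
        assert result["p"] == pytest.approx(count / total, abs=1e-12)

    def test_empty_weight_set_rejected(self, toy_event_table):
        with pytest.raises(ValueError):
            maxcombo(toy_event_table, weight_set=())


class TestTypeIError:
    def test_rejection_rate_at_nominal_level(self):
        # 2000 null replicates, two exponential samples of 50 each
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            t = table(
                rng.exponential(10.0, 100),
                np.ones(100, dtype=int),
                ["a"] * 50 + ["b"] * 50,
            )
            p = weighted_logrank(t, 0.0, 0.0)["p"]
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.04 <= rate <= 0.06


class TestBootstrapSimilarity:
    def test_self_comparison_ratio_high(self):
        sim = event_times_fixture(n=300, shape=1.2, scale=12.0, seed=5)
        report = bootstrap_similarity(sim, sim, n_bootstrap=200, seed=6)
        assert report.similarity_ratio >= 0.95
        assert report.similar

    def test_large_shift_ratio_near_zero(self):
        sim = event_times_fixture(n=300, shape=1.2, scale=12.0, seed=7)
        shifted = sim.copy()
        shifted["time"] = shifted["time"] + 40.0
        report = bootstrap_similarity(sim, shifted, n_bootstrap=200, seed=8)
        assert report.similarity_ratio < 0.05
        assert not report.similar

    def test_decision_threshold_applied(self):
        report = ComparisonReport(
            n_bootstrap=10, subsample_fraction=0.1, alpha=0.05,
            similarity_ratio=0.79, threshold=0.80, similar=0.79 >= 0.80,
            p_values=np.array([]),
        )
        assert not report.similar
        assert report.to_dict()["threshold"] == 0.80

    def test_tiny_subsample_rejected(self):
        sim = event_times_fixture(n=10, seed=9)
        with pytest.raises(ValueError):
            bootstrap_similarity(sim, sim, n_bootstrap=5, subsample_fraction=0.1)


def outcomes(ids, ttps, events, arm="a"):
    return pd.DataFrame({
        "patient": ids, "arm": arm, "ttp_months": ttps, "event": events,
        "cause": ["target_lesion_growth" if e else "none" for e in events],
    })


class TestEffectModel:
    def test_identical_arms_zero_benefit_unit_correlation(self):
        a = outcomes([1, 2, 3], [5.0, 8.0, 12.0], [True, True, True])
        result = effect_model(a, a.copy())
        assert np.allclose(result["paired"]["benefit"], 0.0)
        assert result["pearson"] == pytest.approx(1.0)

    def test_three_pairs_by_hand(self):
        a = outcomes([1, 2, 3], [6.0, 10.0, 20.0], [True] * 3)
        b = outcomes([1, 2, 3], [4.0, 6.0, 10.0], [True] * 3)
        result = effect_model(a, b)
        assert result["median_ttp_a"] == 10.0
        assert result["median_ttp_b"] == 6.0
        assert result["median_benefit"] == 4.0
        cov = np.cov([6.0, 10.0, 20.0], [4.0, 6.0, 10.0])
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert result["ellipse_semi_axes"][0] == pytest.approx(np.sqrt(eig[0]))
        assert result["ellipse_semi_axes"][1] == pytest.approx(np.sqrt(eig[1]))

    def test_censored_patients_excluded_but_tallied(self):
        a = outcomes([1, 2, 3, 4], [5.0, 24.0, 8.0, 9.0],
                     [True, False, True, True])
        b = outcomes([1, 2, 3, 4], [4.0, 6.0, 24.0, 7.0],
                     [True, True, False, True])
        result = effect_model(a, b)
        assert result["n_paired"] == 2  # patients 1 and 4 progressed under both
        assert result["n_nonprogressor_a"] == 1
        assert result["n_nonprogressor_b"] == 1
        assert set(result["paired"]["patient"]) == {1, 4}

    def test_unpaired_ids_rejected(self):
        a = outcomes([1, 2], [5.0, 6.0], [True, True])
        b = outcomes([1, 3], [5.0, 6.0], [True, True])
        with pytest.raises(ValueError):
            effect_model(a, b)
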