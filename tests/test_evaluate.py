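import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from posturekit.annotation import RemovalLog
from posturekit.errors import InsufficientDataError, UndefinedMetricError
from posturekit.evaluate import (
    class_metrics,
    cohen_kappa,
    compare_model_types,
    evaluation_report,
    interval_prevalence,
    kappa_from_confusion,
    landis_koch_bin,
    prevalence_correlation,
    timeline_report,
)


def expand(confusion: dict[tuple[str, str], int]):
    actual, predicted = [], []
    for (a, p), n in confusion.items():
        actual += [a] * n
        predicted += [p] * n
    return np.array(actual, dtype=object), np.array(predicted, dtype=object)


class TestCohenKappa:
    def test_identical_sequences(self):
        a = np.array(["supine", "prone", "held"] * 10, dtype=object)
        assert cohen_kappa(a, a) == pytest.approx(1.0)

    def test_two_by_two_hand_computed(self):
        # po = 0.9, pe = 0.5 -> kappa = 0.8
        a, p = expand({("supine", "supine"): 45, ("supine", "prone"): 5,
                       ("prone", "supine"): 5, ("prone", "prone"): 45})
        assert cohen_kappa(a, p) == pytest.approx(0.80)

    def test_chance_level_agreement_is_zero(self):
        a, p = expand({("supine", "supine"): 25, ("supine", "prone"): 25,
                       ("prone", "supine"): 25, ("prone", "prone"): 25})
        assert cohen_kappa(a, p) == pytest.approx(0.0)

    def test_both_constant_identical_undefined(self):
        a = np.array(["held"] * 10, dtype=object)
        with pytest.raises(UndefinedMetricError):
            cohen_kappa(a, a)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_agrees_with_independent_formula_on_random_confusions(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        counts = rng.integers(0, 30, size=(k, k))
        counts[0, 0] += 1  # non-empty
        conf = pd.DataFrame(counts, index=list("abcd"[:k]), columns=list("abcd"[:k]))
        n = counts.sum()
        po = np.trace(counts) / n
        pe = (counts.sum(1) / n) @ (counts.sum(0) / n)
        if pe >= 1.0:
            return
        assert kappa_from_confusion(conf) == pytest.approx((po - pe) / (1 - pe))

    def test_permuting_class_order_invariant(self):
        rng = np.random.default_rng(0)
        a = rng.choice(["supine", "prone", "sitting"], 200)
        p = rng.choice(["supine", "prone", "sitting"], 200)
        k1 = cohen_kappa(a, p)
        mapping = {"supine": "sitting", "sitting": "prone", "prone": "supine"}
        k2 = cohen_kappa([mapping[x] for x in a], [mapping[x] for x in p])
        assert k2 == pytest.approx(k1)


class TestClassMetrics:
    def test_ppv_seven_of_nine(self):
        conf = pd.DataFrame(
            [[7, 0], [2, 100]],
            index=["upright", "sitting"], columns=["upright", "sitting"],
        )
        m = class_metrics(conf)
        assert m.loc["upright", "ppv"] == pytest.approx(7 / 9, abs=5e-4)

    def test_sensitivity_twentytwo_of_thirtyone(self):
        conf = pd.DataFrame(
            [[22, 9], [0, 50]],
            index=["supine", "sitting"], columns=["supine", "sitting"],
        )
        m = class_metrics(conf)
        assert m.loc["supine", "sensitivity"] == pytest.approx(22 / 31, abs=5e-3)

    def test_diagonal_confusion_perfect(self):
        conf = pd.DataFrame(np.diag([5, 7, 9]), index=list("abc"), columns=list("abc"))
        m = class_metrics(conf)
        assert (m["sensitivity"] == 1.0).all()
        assert (m["ppv"] == 1.0).all()

    def test_never_predicted_class_has_missing_ppv(self):
        conf = pd.DataFrame([[0, 3], [0, 5]], index=list("ab"), columns=list("ab"))
        m = class_metrics(conf)
        assert np.isnan(m.loc["a", "ppv"])
        assert m.loc["a", "sensitivity"] == 0.0

    def test_bounds_and_tp_inequality(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 40, size=(4, 4))
        counts[np.diag_indices(4)] += 1
        conf = pd.DataFrame(counts, index=list("abcd"), columns=list("abcd"))
        m = class_metrics(conf)
        ok = m.dropna()
        assert ((ok["sensitivity"] >= 0) & (ok["sensitivity"] <= 1)).all()
        assert ((ok["ppv"] >= 0) & (ok["ppv"] <= 1)).all()
        tp = np.diag(counts)
        assert (tp <= np.minimum(counts.sum(1), counts.sum(0))).all()

    def test_prevalence_sums_to_100(self):
        a, p = expand({("supine", "supine"): 30, ("held", "held"): 70})
        report = evaluation_report(a, p)
        assert report.per_class["prevalence"].sum() == pytest.approx(100.0)


@pytest.mark.parametrize(
    "kappa,expected",
    [
        (0.70, "Substantial"),
        (0.82, "Almost Perfect"),
        (0.805, "Almost Perfect"),  # rounds half-up to 0.81
        (0.604, "Moderate"),
        (0.10, "Slight to Poor"),
        (-0.3, "Slight to Poor"),
    ],
)
def test_landis_koch_bins(kappa, expected):
    assert landis_koch_bin(kappa) == expected


class TestPrevalenceCorrelation:
    def test_identical_proportions_r_one(self):
        props = pd.DataFrame(
            {"supine": [0.1, 0.3, 0.5], "held": [0.9, 0.7, 0.5]}, index=["a", "b", "c"]
        )
        per_class, pooled = prevalence_correlation(props, props)
        assert pooled == pytest.approx(1.0)
        assert all(r == pytest.approx(1.0) for r in per_class.values())

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(5)
        actual = pd.DataFrame(rng.uniform(size=(17, 3)), columns=list("abc"))
        predicted = actual + rng.normal(scale=0.05, size=actual.shape)
        per_class, pooled = prevalence_correlation(actual, predicted)
        for cls in "abc":
            expected = sps.pearsonr(actual[cls], predicted[cls]).statistic
            assert per_class[cls] == pytest.approx(expected)
        expected_pooled = sps.pearsonr(
            actual.to_numpy().ravel(), predicted.to_numpy().ravel()
        ).statistic
        assert pooled == pytest.approx(expected_pooled)

    def test_constant_actual_gives_missing_r(self):
        actual = pd.DataFrame({"a": [0.5, 0.5, 0.5]})
        predicted = pd.DataFrame({"a": [0.4, 0.5, 0.6]})
        per_class, _ = prevalence_correlation(actual, predicted)
        assert np.isnan(per_class["a"])

    def test_too_few_observations_rejected(self):
        props = pd.DataFrame({"a": [0.1, 0.2]})
        with pytest.raises(InsufficientDataError):
            prevalence_correlation(props, props)


class TestIntervalPrevalence:
    def test_partitions_and_proportions(self):
        starts = np.arange(0, 900, 1.0)
        labels = np.where(starts < 450, "sitting", "prone").astype(object)
        table = interval_prevalence(starts, labels, interval_s=450.0)
        assert len(table) == 2
        assert table.loc[0, "sitting"] == pytest.approx(1.0)
        assert table.loc[1, "prone"] == pytest.approx(1.0)


class TestCompareModelTypes:
    def test_zero_differences_undefined(self):
        x = [0.9, 0.8, 0.7]
        with pytest.raises(UndefinedMetricError):
            compare_model_types(x, x)

    def test_hand_computed_three_pairs(self):
        first = np.array([0.8, 0.9, 0.7])
        second = np.array([0.9, 0.95, 0.8])
        d = first - second
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        report = compare_model_types(first, second)
        assert report.t == pytest.approx(expected_t)
        assert report.df == 2

    def test_direction_of_sign(self):
        report = compare_model_types([0.5, 0.6, 0.55], [0.9, 0.95, 0.92])
        assert report.t < 0  # first worse than second


class TestTimelineReport:
    def test_all_one_label_single_episode(self):
        starts = np.arange(0, 60, 1.0)
        labels = np.array(["sitting"] * 60, dtype=object)
        table, percents = timeline_report(starts, labels)
        assert len(table) == 1
        assert percents["sitting"] == pytest.approx(100.0)

    def test_alternating_labels_one_second_episodes(self):
        starts = np.arange(0, 10, 1.0)
        labels = np.array(["sitting", "held"] * 5, dtype=object)
        table, _ = timeline_report(starts, labels)
        assert len(table) == 10
        assert ((table["end_s"] - table["start_s"]) == 1.0).all()

    def test_removal_log_creates_gap_and_totals_sum_to_100(self):
        starts = np.arange(0, 100, 1.0)
        labels = np.array(["held"] * 50 + ["prone"] * 50, dtype=object)
        table, percents = timeline_report(
            starts, labels, removal_log=RemovalLog([(20.0, 30.0, "nap")])
        )
        assert "none" in set(table["label"])
        assert sum(percents.values()) == pytest.approx(100.0)


def test_report_confusion_row_sums_match_actual_counts():
    rng = np.random.default_rng(9)
    a = rng.choice(["supine", "prone", "held"], 300)
    p = rng.choice(["supine", "prone", "held"], 300)
    report = evaluation_report(a, p)
    for cls in report.confusion.index:
        assert report.confusion.loc[cls].sum() == (a == cls).sum()
    assert report.accuracy == pytest.approx((a == p).mean())
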