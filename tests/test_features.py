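import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from posturekit.errors import ConfigError
from posturekit.features import (
    STAT_NAMES,
    base_features,
    build_registry,
    derived_features,
    featurize,
    feature_columns,
)
from posturekit.windowing import LabeledWindow

RNG = np.random.default_rng(12)


def make_window(samples_by_placement, label="sitting"):
    first = next(iter(samples_by_placement.values()))
    return LabeledWindow(
        start=0.0, index=0, length=len(first), samples=samples_by_placement, label=label
    )


def single_registry():
    return build_registry("custom", placements=("right_hip",))


class TestRegistryCounts:
    def test_lab3_base_and_total(self):
        r = build_registry("lab3")
        assert r.n_base == 180
        assert r.size == 204

    def test_home4_counts_match_enumeration(self):
        r = build_registry("home4")
        assert r.n_base == 10 * 4 * 2 * 3 == 240
        # derived: cross-sensor sum+magnitude (2*6) + cross-axis sum+magnitude (2*4*2)
        assert r.size == 240 + 12 + 16

    def test_single_placement_profile(self):
        r = single_registry()
        assert r.n_base == 60
        assert r.size == 64  # no cross-sensor group; 2x2 cross-axis features

    def test_names_unique_and_order_stable(self):
        a, b = build_registry("lab3"), build_registry("lab3")
        assert len(set(a.names)) == a.size
        assert a.names == b.names
        assert a.hash == b.hash

    def test_optional_groups_change_hash_and_size(self):
        base = build_registry("lab3")
        ext = build_registry("lab3", include_correlations=True, include_differences=True)
        assert ext.size > base.size
        assert ext.hash != base.hash


class TestBaseFeatures:
    def test_constant_channel_degenerate_statistics(self):
        c = 0.37
        w = make_window({"right_hip": np.full((200, 6), c)})
        r = single_registry()
        vec = dict(zip([e.name for e in r.entries if e.kind == "base_stat"], base_features(w, r)))
        for stat, expected in [
            ("mean", c), ("median", c), ("min", c), ("max", c),
            ("p25", c), ("p75", c), ("sd", 0.0), ("skew", 0.0),
            ("kurtosis", 0.0), ("sum", c * 200),
        ]:
            assert vec[f"right_hip_accel_x_{stat}"] == pytest.approx(expected)

    def test_sine_window_matches_brute_force(self):
        t = np.arange(200) / 50.0
        x = 0.7 * np.sin(2 * np.pi * 1.0 * t) + 0.1
        block = np.zeros((200, 6))
        block[:, 0] = x
        r = single_registry()
        vec = dict(zip(r.names, np.concatenate([base_features(make_window({"right_hip": block}), r),
                                                derived_features(make_window({"right_hip": block}), r)])))
        oracle = {
            "mean": x.mean(),
            "sd": x.std(ddof=1),
            "skew": sps.skew(x),
            "kurtosis": sps.kurtosis(x),
            "min": x.min(),
            "median": np.median(x),
            "max": x.max(),
            "p25": np.percentile(x, 25),
            "p75": np.percentile(x, 75),
            "sum": x.sum(),
        }
        for stat in STAT_NAMES:
            assert vec[f"right_hip_accel_x_{stat}"] == pytest.approx(oracle[stat], abs=1e-10)

    def test_zero_window_zero_derived(self):
        w = make_window({"right_hip": np.zeros((200, 6))})
        assert np.all(derived_features(w, single_registry()) == 0.0)


class TestDerivedFeatures:
    def test_cross_sums_and_magnitudes_from_window_sums(self):
        r = build_registry("lab3")
        blocks = {p: RNG.normal(size=(200, 6)) for p in r.placements}
        w = make_window(blocks)
        vec = dict(zip(r.names, np.concatenate([base_features(w, r), derived_features(w, r)])))
        sums = {p: blocks[p].sum(axis=0) for p in r.placements}
        # cross-sensor on accel x (channel 0)
        expected_sum = sum(sums[p][0] for p in r.placements)
        expected_mag = np.sqrt(sum(sums[p][0] ** 2 for p in r.placements))
        assert vec["all_accel_x_sum"] == pytest.approx(expected_sum)
        assert vec["all_accel_x_magnitude"] == pytest.approx(expected_mag)
        # cross-axis on the hip gyro (channels 3..5)
        gy = sums["right_hip"][3:6]
        assert vec["right_hip_gyro_axes_sum"] == pytest.approx(gy.sum())
        assert vec["right_hip_gyro_axes_magnitude"] == pytest.approx(np.sqrt((gy**2).sum()))

    def test_correlation_features_match_pearson(self):
        r = build_registry("custom", placements=("right_hip",), include_correlations=True)
        block = RNG.normal(size=(200, 6))
        w = make_window({"right_hip": block})
        x = np.concatenate([base_features(w, r), derived_features(w, r)])
        vec = dict(zip(r.names, x))
        expected = sps.pearsonr(block[:, 0], block[:, 1]).statistic
        assert vec["right_hip_accel_x_y_corr"] == pytest.approx(expected, abs=1e-10)


class TestFeaturize:
    def _windows(self, n):
        out = []
        for i in range(n):
            out.append(
                LabeledWindow(
                    start=float(n - i), index=0, length=200,
                    samples={"right_hip": RNG.normal(size=(200, 6))}, label="held",
                )
            )
        return out

    def test_empty_input_empty_table(self):
        table = featurize([], single_registry())
        assert len(table) == 0
        assert len(feature_columns(table)) == 64

    def test_rows_ordered_by_start_and_sized_by_registry(self):
        r = single_registry()
        table = featurize(self._windows(5), r)
        assert len(table) == 5
        assert list(table["start_s"]) == sorted(table["start_s"])
        assert len(feature_columns(table)) == r.size
        assert table.attrs["registry_hash"] == r.hash

    def test_excluded_windows_omitted(self):
        from posturekit.windowing import ExclusionReason

        windows = self._windows(4)
        windows[0].label = None
        windows[0].excluded_reason = ExclusionReason.NO_MAJORITY
        assert len(featurize(windows, single_registry())) == 3

    def test_missing_placement_raises(self):
        with pytest.raises(ConfigError):
            featurize(self._windows(1), build_registry("lab3"))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(k=st.floats(0.1, 100.0), seed=st.integers(0, 1000))
def test_scaling_property(k, seed):
    """Scaling all channels by k scales location/scale statistics by k and
    leaves the shape statistics (skew, kurtosis) unchanged."""
    rng = np.random.default_rng(seed)
    block = rng.normal(size=(200, 6))
    r = single_registry()
    w1 = make_window({"right_hip": block})
    w2 = make_window({"right_hip": k * block})
    v1 = dict(zip(r.names, np.concatenate([base_features(w1, r), derived_features(w1, r)])))
    v2 = dict(zip(r.names, np.concatenate([base_features(w2, r), derived_features(w2, r)])))
    for name, x in v1.items():
        if name.endswith(("_skew", "_kurtosis")):
            assert v2[name] == pytest.approx(x, abs=1e-8)
        else:
            assert v2[name] == pytest.approx(k * x, rel=1e-8, abs=1e-8)


def test_features_invariant_to_window_start():
    block = RNG.normal(size=(200, 6))
    r = single_registry()
    w1 = LabeledWindow(start=0.0, index=0, length=200, samples={"right_hip": block}, label="held")
    w2 = LabeledWindow(start=123.0, index=999, length=200, samples={"right_hip": block}, label="held")
    t1 = featurize([w1], r)
    t2 = featurize([w2], r)
    np.testing.assert_array_equal(
        t1[feature_columns(t1)].to_numpy(), t2[feature_columns(t2)].to_numpy()
    )
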