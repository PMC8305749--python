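import numpy as np
import pandas as pd
import pytest

from driverisk.errors import DataError, DomainError
from driverisk.features import (
    build_feature_table,
    dft_amplitudes,
    feature_columns,
    recursive_feature_elimination,
    summary_stats,
)


def brute_force_dft(x):
    """Direct evaluation of the transform sum (the independent oracle)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    return np.array(
        [sum(x[m] * np.exp(-2j * np.pi * k * m / n) for m in range(n)) for k in range(n)]
    )


class TestDFTAmplitudes:
    def test_constant_series_all_zero(self):
        assert np.allclose(dft_amplitudes(np.full(100, 7.3)), 0.0)

    def test_two_point_series_matches_brute_force(self):
        # raw transform of (1, -1): bin 0 -> 0, bin 1 -> 2
        raw = brute_force_dft([1.0, -1.0])
        assert abs(raw[0]) == pytest.approx(0.0, abs=1e-12)
        assert abs(raw[1]) == pytest.approx(2.0, abs=1e-12)

    def test_sinusoid_peaks_at_its_frequency(self):
        dt = 0.04
        t = np.arange(0, 100, dt)
        x = np.sin(2 * np.pi * 0.08 * t)
        amps = dft_amplitudes(x, dt=dt)
        assert int(np.argmax(amps)) == 1  # 0-based position of the 0.08 Hz grid point
        assert amps[1] == pytest.approx(0.5, abs=0.01)  # |rfft|/N of a unit sinusoid

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        n = len(x)
        raw = np.abs(brute_force_dft(x - x.mean()))[: n // 2 + 1] / n
        freqs = np.arange(n // 2 + 1) / (n * 0.04)
        grid = 0.04 * np.arange(1, 21)
        expected = np.interp(grid, freqs, raw)
        assert np.allclose(dft_amplitudes(x), expected, atol=1e-9)

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        assert np.allclose(dft_amplitudes(x), dft_amplitudes(x + 123.4), atol=1e-9)

    def test_scaling_scales_amplitudes(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        assert np.allclose(dft_amplitudes(-3.0 * x), 3.0 * dft_amplitudes(x), atol=1e-9)

    def test_length_invariance_of_fixed_grid(self):
        # the same continuous signal observed for 20 s vs 40 s lands on the
        # same grid features (within interpolation tolerance)
        dt = 0.04
        f0 = 0.2
        t20 = np.arange(0, 20, dt)
        t40 = np.arange(0, 40, dt)
        a20 = dft_amplitudes(np.sin(2 * np.pi * f0 * t20), dt=dt)
        a40 = dft_amplitudes(np.sin(2 * np.pi * f0 * t40), dt=dt)
        assert np.argmax(a20) == np.argmax(a40) == 4  # 0.2 Hz grid point
        assert a20[4] == pytest.approx(a40[4], abs=0.05)

    def test_short_series_rejected(self):
        with pytest.raises(DomainError):
            dft_amplitudes([1.0])


class TestSummaryStats:
    def test_constant_series(self):
        assert summary_stats([2.0, 2.0, 2.0]) == pytest.approx((2.0, 0.0, 0.0))

    def test_two_point_sample_sd(self):
        mean, sd, cv = summary_stats([1.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(np.std([1.0, 3.0], ddof=1))
        assert cv == pytest.approx(sd / 2.0)

    def test_zero_mean_cv_guard(self):
        _, _, cv = summary_stats([-1.0, 1.0])
        assert cv == 0.0


class TestFeatureTable:
    @staticmethod
    def _signals(vids, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return {
            vid: {
                "lon_speed": rng.normal(25, 1, n),
                "lat_speed": rng.normal(0, 0.1, n),
                "gap": rng.uniform(10, 50, n),
            }
            for vid in vids
        }

    def test_default_column_count_is_69_plus_label(self):
        sigs = self._signals([1, 2])
        df = build_feature_table(sigs, {1: 0, 2: 1})
        assert df.shape == (2, 70)
        assert list(df.columns) == feature_columns(20) + ["label"]

    def test_n_dft_21_gives_72_features(self):
        sigs = self._signals([1, 2])
        df = build_feature_table(sigs, {1: 0, 2: 1}, n_dft=21)
        assert df.shape[1] - 1 == 72

    def test_row_order_equivariance(self):
        sigs = self._signals([1, 2, 3])
        labels = {1: 0, 2: 1, 3: 0}
        a = build_feature_table(sigs, labels)
        b = build_feature_table({k: sigs[k] for k in [3, 1, 2]}, labels)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_missing_signal_lists_driver(self):
        sigs = self._signals([1, 2])
        del sigs[2]["gap"]
        with pytest.raises(DataError, match="2"):
            build_feature_table(sigs, {1: 0, 2: 1})

    def test_amplitudes_non_negative(self):
        df = build_feature_table(self._signals([1, 2, 3]), {1: 0, 2: 1, 3: 0})
        dft_cols = [c for c in df.columns if "_dft" in c]
        assert (df[dft_cols] >= 0).all().all()


class TestRFE:
    @staticmethod
    def _planted_table(n=200, noise_features=9, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < 0.3).astype(int)
        X = rng.normal(size=(n, noise_features + 1))
        X[:, 0] = y * 4.0 + rng.normal(0, 0.3, n)  # near-perfect separator
        cols = ["signal"] + [f"noise{i}" for i in range(noise_features)]
        df = pd.DataFrame(X, columns=cols)
        df["label"] = y
        return df

    def test_informative_feature_survives(self, small_booster):
        df = self._planted_table()
        res = recursive_feature_elimination(df, evaluator=small_booster, cv=3, seed=0)
        assert "signal" in res.selected

    def test_unbounded_patience_eliminates_all_but_one(self, small_booster):
        df = self._planted_table(n=120, noise_features=4)
        res = recursive_feature_elimination(
            df, evaluator=small_booster, cv=3, patience=None, seed=0
        )
        assert len(res.elimination_order) == 4  # n_features - 1
        assert len(res.score_trace) == 5

    def test_duplicated_column_redundancy_removed_information_kept(self, small_booster):
        df = self._planted_table(n=150, noise_features=3)
        df.insert(1, "signal_copy", df["signal"].to_numpy())
        cols = [c for c in df.columns if c != "label"] + ["label"]
        res = recursive_feature_elimination(
            df[cols], evaluator=small_booster, cv=3, patience=None, seed=0
        )
        # the pair is redundant: dropping one member cannot hurt, so at
        # least one is eliminated while the information survives in the other
        assert "signal" in res.elimination_order or "signal_copy" in res.elimination_order
        pair_drop = min(
            (res.elimination_order.index(c) for c in ("signal", "signal_copy")
             if c in res.elimination_order),
        )
        survivors_at_drop = res.score_trace[pair_drop + 1]
        assert survivors_at_drop >= res.score_trace[0] - 0.15

    def test_single_class_rejected(self, small_booster):
        df = self._planted_table(n=50)
        df["label"] = 0
        with pytest.raises(DomainError):
            recursive_feature_elimination(df, evaluator=small_booster)
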