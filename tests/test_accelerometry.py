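"""ODBA window operator, windowing, daily aggregation, deployment mean."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odee import accelerometry as acc
from odee.synthetic import SimConfig, simulate_accel_trace

from conftest import make_deployment


def brute_force_odba(counts, adc_basis=2 ** 14, window=50, midpoint="range"):
    """Naive per-window reference: explicit loops, no vectorisation."""
    n_windows = counts.shape[1] // window
    out = []
    for w in range(n_windows):
        total = 0.0
        for c in range(3):
            seg = [float(v) for v in counts[c, w * window:(w + 1) * window]]
            mean = sum(seg) / len(seg)
            if midpoint == "range":
                mid = (max(seg) + min(seg)) / 2.0
            else:
                mid = 0.0
            total += abs(mean - mid)
        out.append(total / adc_basis)
    return np.array(out)


class TestOdbaWindow:
    def test_hand_example(self):
        # one channel: 40 samples at 0, 10 at full scale; others constant
        x = np.array([0] * 40 + [16384] * 10)
        window = np.vstack([x, np.full(50, 123), np.full(50, -7)])
        assert acc.odba_window(window) == pytest.approx(0.3, abs=1e-12)

    @pytest.mark.parametrize("level", [-5000, 0, 1, 9999])
    def test_constant_window_is_zero(self, level):
        window = np.full((3, 50), level)
        assert acc.odba_window(window) == 0.0

    def test_negation_symmetry(self, rng):
        window = rng.integers(-8000, 8000, size=(3, 50))
        assert acc.odba_window(-window) == pytest.approx(
            acc.odba_window(window), abs=1e-15
        )

    def test_matches_brute_force(self, rng):
        counts = rng.integers(-8000, 8000, size=(3, 50 * 40))
        fast = [
            acc.odba_window(counts[:, i * 50:(i + 1) * 50])
            for i in range(40)
        ]
        np.testing.assert_allclose(fast, brute_force_odba(counts), rtol=0, atol=0)

    @given(offset=st.integers(-4000, 4000), data=st.data())
    @settings(max_examples=25, deadline=None)
    def test_offset_invariance_in_range_mode(self, offset, data):
        """Adding a per-channel constant must not change range-mode ODBA."""
        base = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(-2000, 2000), min_size=10, max_size=10),
                    min_size=3,
                    max_size=3,
                )
            )
        )
        shifted = base + np.array([[offset], [0], [-offset]])
        assert acc.odba_window(shifted) == pytest.approx(
            acc.odba_window(base), abs=1e-9
        )

    def test_fixed_midpoint_mode(self):
        window = np.vstack(
            [np.full(10, 100), np.full(10, -100), np.zeros(10)]
        )
        # fixed midpoint 0: |100| + |-100| + 0 over basis
        got = acc.odba_window(window, midpoint_mode="fixed")
        assert got == pytest.approx(200 / 2 ** 14)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            acc.odba_window(np.zeros((3, 1)))
        with pytest.raises(ValueError, match="channel"):
            acc.odba_window(np.zeros((2, 50)))

    def test_nonnegative_and_zero_iff_mean_equals_midpoint(self, rng):
        for _ in range(50):
            w = rng.integers(-500, 500, size=(3, 20))
            v = acc.odba_window(w)
            assert v >= 0
            means = w.mean(axis=1)
            mids = (w.max(axis=1) + w.min(axis=1)) / 2
            assert (v == 0) == bool(np.all(means == mids))


class TestWindowize:
    @pytest.mark.parametrize("n,expected", [(250, 5), (249, 4), (50, 1)])
    def test_counts(self, n, expected):
        dep = make_deployment(np.zeros((3, n), dtype=int))
        windows, starts = acc.windowize(dep)
        assert len(windows) == expected == len(starts)

    def test_counts_match_index_arithmetic(self, rng):
        for n in rng.integers(50, 5000, size=100):
            dep = make_deployment(np.zeros((3, int(n)), dtype=int))
            windows, _ = acc.windowize(dep)
            assert len(windows) == int(n) // 50

    def test_window_starts_spacing(self):
        dep = make_deployment(np.zeros((3, 300), dtype=int))
        _, starts = acc.windowize(dep)
        assert (np.diff(starts) == pd.Timedelta(seconds=2)).all()

    def test_bad_window_errors(self):
        dep = make_deployment(np.zeros((3, 100), dtype=int))
        with pytest.raises(ValueError):
            acc.windowize(dep, window_s=0)


class TestAggregateDaily:
    def _series(self, n_days, per_day=4, value=None, rng=None):
        starts = pd.date_range("2019-05-01", periods=n_days * per_day,
                               freq=f"{24 // per_day}h")
        if value is not None:
            vals = np.full(len(starts), value)
        else:
            vals = rng.uniform(0, 1, size=len(starts))
        return vals, starts

    def test_edge_trimming(self):
        vals, starts = self._series(8, value=0.5)
        daily = acc.aggregate_daily(vals, starts)
        assert len(daily) == 8
        assert daily["retained"].sum() == 6
        assert not daily["retained"].iloc[0] and not daily["retained"].iloc[-1]

    def test_constant_value_passthrough(self):
        vals, starts = self._series(5, value=0.25)
        daily = acc.aggregate_daily(vals, starts)
        assert np.allclose(daily["odba_d"], 0.25)
        assert acc.deployment_odba(daily) == pytest.approx(0.25)

    def test_matches_groupby_oracle(self, rng):
        vals, starts = self._series(6, per_day=8, rng=rng)
        daily = acc.aggregate_daily(vals, starts)
        expected = (
            pd.Series(vals, index=pd.DatetimeIndex(starts).normalize())
            .groupby(level=0)
            .mean()
        )
        np.testing.assert_allclose(daily["odba_d"], expected.values)

    def test_too_few_days(self):
        vals, starts = self._series(2, value=0.1)
        with pytest.raises(ValueError, match="no retained days"):
            acc.aggregate_daily(vals, starts)

    def test_noon_boundary_shifts_days(self):
        starts = pd.date_range("2019-05-01 06:00", periods=96, freq="1h")
        vals = np.ones(96)
        midnight = acc.aggregate_daily(vals, starts, day_boundary="midnight")
        noon = acc.aggregate_daily(vals, starts, day_boundary="noon")
        assert not midnight["day"].equals(noon["day"])


class TestDeploymentOdba:
    def test_mean_and_identity(self):
        daily = pd.DataFrame(
            {"odba_d": [0.9, 0.2, 0.4, 0.9], "retained": [False, True, True, False]}
        )
        assert acc.deployment_odba(daily) == pytest.approx(0.3)
        single = pd.DataFrame({"odba_d": [0.7], "retained": [True]})
        assert acc.deployment_odba(single) == 0.7

    def test_permutation_invariance(self, rng):
        vals = rng.uniform(0, 1, 6)
        a = pd.DataFrame({"odba_d": vals, "retained": True})
        b = pd.DataFrame({"odba_d": rng.permutation(vals), "retained": True})
        assert acc.deployment_odba(a) == pytest.approx(acc.deployment_odba(b))


class TestPipelineAgainstOracle:
    def test_synthetic_deployment_exact_match(self):
        cfg = SimConfig(seed=11)
        dep, truth = simulate_accel_trace(cfg, deployment_days=3)
        series = acc.compute_odba(dep)
        # exact equality with naive per-window recomputation on a slice
        oracle = brute_force_odba(dep.counts[:, : 50 * 2000])
        np.testing.assert_array_equal(series.window_values[:2000], oracle)

    def test_measured_close_to_analytic_truth(self):
        cfg = SimConfig(seed=12)
        dep, truth = simulate_accel_trace(cfg, deployment_days=3)
        series = acc.compute_odba(dep)
        # jitter and integer rounding add <1% to the oscillatory component
        assert series.odba_i == pytest.approx(
            truth["odba_i_expected"], rel=0.01
        )
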