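"""Growth-curve transforms and the lagVstall / colony-fitness metrics."""

import numpy as np
import pytest

from colonylapse.curves import (
    DeadColonyError,
    GrowthCurve,
    ShortCurveError,
    colony_fitness,
    compute_metrics,
    deviation_profile,
    endpoint_normalize,
    growth_rate,
    lag_v_stall,
    reference_curve,
    rlowess_batch,
    smooth_curve,
    truncate_curve,
    zero_normalize,
)


def _curve(values, dt=5.0, **ids):
    values = np.asarray(values, dtype=float)
    return GrowthCurve(np.arange(values.size) * dt, values, **ids)


class TestTruncate:
    def test_48hr_series_truncated_to_481_frames(self):
        c = _curve(np.arange(577))  # 48 hr at 5-min spacing, frame 1 at t=0
        assert len(truncate_curve(c, 40.0)) == 481

    def test_short_series_unchanged(self):
        c = _curve(np.arange(121))  # 10 hr
        assert truncate_curve(c, 40.0) is c

    def test_overtight_truncation_raises(self):
        with pytest.raises(ShortCurveError):
            truncate_curve(_curve(np.arange(577)), 0.05)


class TestSmoothing:
    def test_linear_ramp_reproduced_exactly(self):
        c = _curve(3.0 + 2.0 * np.arange(200))
        out = smooth_curve(c, window=48)
        assert np.allclose(out.values, c.values, atol=1e-6)

    def test_window_one_is_identity(self):
        c = _curve(np.random.default_rng(0).uniform(0, 10, 50))
        assert np.array_equal(smooth_curve(c, window=1).values, c.values)

    def test_large_spike_robustly_downweighted(self):
        rng = np.random.default_rng(1)
        sigma = 0.5
        ramp = 2.0 * np.arange(300) + rng.normal(0, sigma, 300)
        ramp[150] += 50 * sigma
        out = smooth_curve(_curve(ramp), window=48)
        assert abs(out.values[150] - 2.0 * 150) < 2 * sigma

    def test_agrees_with_iterated_bisquare_oracle(self):
        # independent oracle: naive per-point loop with the same kernel,
        # local linear fit and local-MAR bisquare reweighting
        rng = np.random.default_rng(2)
        y = np.sin(np.arange(80) / 10.0) * 10 + rng.normal(0, 0.3, 80)
        window, iters = 16, 3
        half_l = window // 2
        pad_r = window - 1 - half_l

        def wls(idx, weights):
            lo, hi = max(0, idx - half_l), min(80, idx + pad_r + 1)
            xs = np.arange(lo, hi) - idx
            dmax = np.abs(xs).max()
            kern = np.maximum((1 - (np.abs(xs) / dmax) ** 3) ** 3, 1e-6)
            w = kern * weights[lo:hi]
            A = np.vstack([np.ones_like(xs), xs]).T
            beta = np.linalg.lstsq(A * np.sqrt(w)[:, None],
                                   y[lo:hi] * np.sqrt(w), rcond=None)[0]
            return beta[0]

        robust = np.ones(80)
        for it in range(iters + 1):
            fit = np.array([wls(i, robust) for i in range(80)])
            if it == iters:
                break
            resid = y - fit
            pad = np.pad(np.abs(resid), (half_l, pad_r), mode="edge")
            scale = np.array([6 * np.median(pad[i:i + window]) for i in range(80)])
            u = np.clip(resid / np.where(scale == 0, np.inf, scale), -1, 1)
            robust = (1 - u * u) ** 2
        ours = rlowess_batch(y[None, :], window, iters)[0]
        assert np.allclose(ours, fit, atol=1e-8)

    def test_batch_matches_single_curve_path(self):
        rng = np.random.default_rng(3)
        mat = rng.uniform(0, 100, (5, 120))
        batch = rlowess_batch(mat, 48)
        for i in range(5):
            single = smooth_curve(_curve(mat[i]), 48)
            assert np.allclose(batch[i], single.values)


class TestNormalizations:
    def test_zero_normalize_subtracts_first_value(self):
        assert np.allclose(zero_normalize(_curve([5, 7, 10])).values, [0, 2, 5])

    def test_zero_normalize_clips_negatives(self):
        assert np.allclose(zero_normalize(_curve([5, 4, 10])).values, [0, 0, 5])

    def test_constant_curve_becomes_all_zero(self):
        assert np.allclose(zero_normalize(_curve([3, 3, 3])).values, 0.0)

    def test_endpoint_normalize_final_is_exactly_one(self):
        out = endpoint_normalize(_curve([0, 2, 5]))
        assert np.allclose(out.values, [0, 0.4, 1])
        assert out.values[-1] == 1.0

    def test_endpoint_normalize_idempotent(self):
        once = endpoint_normalize(_curve([0, 2, 5]))
        twice = endpoint_normalize(once)
        assert np.array_equal(once.values, twice.values)

    def test_dead_colony_excluded(self):
        with pytest.raises(DeadColonyError):
            endpoint_normalize(_curve([0, 0, 0]))
        with pytest.raises(DeadColonyError):
            endpoint_normalize(_curve([0, 1, 2]), min_final_intensity=5.0)


class TestReferenceAndDeviation:
    def test_identical_curves_give_that_curve(self):
        c = endpoint_normalize(_curve([0, 2, 5]))
        ref = reference_curve([c, c, c])
        assert np.allclose(ref.values, c.values)

    def test_pointwise_median(self):
        curves = [endpoint_normalize(_curve([0, v, 1]))
                  for v in (0.2, 0.5, 0.9)]
        assert reference_curve(curves).values[1] == 0.5

    def test_median_stable_under_median_augmentation(self):
        curves = [endpoint_normalize(_curve([0, v, 1])) for v in (0.2, 0.5, 0.9)]
        ref = reference_curve(curves)
        again = reference_curve(curves + [ref])
        assert np.allclose(again.values, ref.values)

    def test_deviation_zero_for_reference_itself(self):
        c = endpoint_normalize(_curve([0, 2, 5]))
        ref = reference_curve([c, c, c])
        assert np.allclose(deviation_profile(c, ref).values, 0.0)

    def test_deviation_antisymmetric_pair(self):
        ref = endpoint_normalize(_curve([0, 0.5, 1]))
        up = _curve([0.0, 0.6, 1.0])
        down = _curve([0.0, 0.4, 1.0])
        d_up = deviation_profile(up, ref).values
        d_down = deviation_profile(down, ref).values
        assert np.allclose(d_up, -d_down)


class TestMetrics:
    def test_lag_v_stall_sums_signed_deviations(self):
        prof = _curve(np.full(432, 0.01))
        assert np.isclose(lag_v_stall(prof), 4.32)
        assert lag_v_stall(_curve(np.zeros(10))) == 0.0

    def test_colony_fitness_is_final_value(self):
        assert colony_fitness(_curve([0, 2, 5])) == 5.0
        assert colony_fitness(_curve([0, 0, 0])) == 0.0

    def test_growth_rate_linear_and_constant(self):
        ramp = _curve(2.0 * np.arange(50) * 5.0)  # slope 2 per minute
        assert np.allclose(growth_rate(ramp), 2.0)
        assert np.allclose(growth_rate(_curve(np.full(50, 7.0))), 0.0)

    def test_growth_rate_peaks_at_logistic_inflection(self):
        t = np.arange(0, 2400, 5.0)
        tm = 1200.0
        c = GrowthCurve(t, 1e5 / (1 + np.exp(-0.01 * (t - tm))))
        rate = growth_rate(c)
        t_peak = t[np.argmax(rate)]
        assert abs(t_peak - tm) <= 5.0  # within one frame
        # oracle: the analytic derivative peaks at the midpoint
        analytic = 1e5 * 0.01 * np.exp(-0.01 * (t - tm)) / (1 + np.exp(-0.01 * (t - tm))) ** 2
        assert abs(rate[240] - analytic[240]) < 0.01 * analytic[240]


class TestPipeline:
    def test_identical_plate_gives_zero_lag_v_stall(self, tiny_experiment):
        import pandas as pd
        t = np.arange(200) * 5.0
        base = 1e4 / (1 + np.exp(-0.01 * (t - 500)))
        meta = pd.DataFrame({
            "strain_id": [f"s{i}" for i in range(6)],
            "plate_id": "p0", "condition": "untreated",
            "replicate": range(6),
        })
        values = np.tile(base, (6, 1))
        out = compute_metrics(meta, values, t)
        assert np.allclose(out["lag_v_stall"], 0.0)
        assert (out["colony_fitness"] > 0).all()

    def test_noiseless_classes_have_expected_signs(self, tiny_experiment):
        exp = tiny_experiment
        m = compute_metrics(exp.meta, exp.values, exp.times)
        ut = m[m["condition"] == "untreated"]
        med = ut.groupby("class_label")["lag_v_stall"].median()
        assert med["lag"] < 0
        assert med["stall"] > 0
        assert np.isclose(med["reference"], 0.0, atol=1e-9)

    def test_per_plate_lag_v_stall_centered(self, rng):
        # symmetric noise around one shared curve: plate mean deviation
        # stays well inside the deviation spread (median centering)
        import pandas as pd
        t = np.arange(300) * 5.0
        base = 1e4 / (1 + np.exp(-0.008 * (t - 700)))
        n = 200
        values = np.clip(base[None, :] + rng.normal(0, 200.0, (n, t.size)), 0, None)
        meta = pd.DataFrame({
            "strain_id": [f"s{i}" for i in range(n)],
            "plate_id": "p0", "condition": "untreated", "replicate": 0,
        })
        out = compute_metrics(meta, values, t)
        lvs = out["lag_v_stall"].to_numpy()
        assert abs(lvs.mean()) < 0.1 * lvs.std()
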