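"""Heart-rate stage: imputation, baseline scaling, AUC and the GLM."""

import numpy as np
import pytest
import statsmodels.api as sm

from magnetoadrenal import heart_rate as hr
from magnetoadrenal.cohort import HeartRateModel, gen_heart_rate


def make_trace(bpm, times=None, **kw):
    bpm = np.asarray(bpm, dtype=float)
    times = np.arange(bpm.size, dtype=float) if times is None else times
    return hr.HeartRateTrace(times=times, bpm=bpm, **kw)


def full_length_trace(fill=360.0):
    return make_trace(np.full(421, fill))


class TestImpute:
    def test_gap_free_trace_unchanged(self):
        tr = full_length_trace()
        out = hr.impute_gaps(tr)
        assert np.array_equal(out.bpm, tr.bpm)

    def test_idempotent(self):
        bpm = np.full(421, 350.0)
        bpm[100:120] = np.nan
        once = hr.impute_gaps(make_trace(bpm))
        twice = hr.impute_gaps(once)
        assert np.allclose(once.bpm, twice.bpm)

    def test_linear_ramp_gap_close_to_interpolation(self):
        t = np.arange(421.0)
        ramp = 300.0 + 60.0 * t / 420.0
        bpm = ramp.copy()
        bpm[200:220] = np.nan
        out = hr.impute_gaps(make_trace(bpm, times=t))
        linear = ramp[200:220]
        assert np.max(np.abs(out.bpm[200:220] - linear)) < 2.0

    def test_observed_values_untouched(self, rng):
        trace, _ = gen_heart_rate(HeartRateModel(gap_rate=0.2), rng, "r", "active", 1)
        obs = np.isfinite(trace.bpm)
        out = hr.impute_gaps(trace)
        assert np.array_equal(out.bpm[obs], trace.bpm[obs])
        assert np.all(np.isfinite(out.bpm))

    def test_majority_missing_rejected(self, rng):
        bpm = np.full(421, 350.0)
        drop = rng.random(421) < 0.6
        drop[:11] = drop[-11:] = False
        bpm[drop] = np.nan
        if np.mean(~np.isfinite(bpm)) > 0.5:
            with pytest.raises(ValueError, match="unable to impute"):
                hr.impute_gaps(make_trace(bpm))

    def test_all_missing_rejected(self):
        bpm = np.full(421, np.nan)
        with pytest.raises(ValueError, match="unable to impute"):
            hr.impute_gaps(make_trace(bpm))

    def test_matches_statsmodels_local_level(self, rng):
        # independent route: statsmodels UnobservedComponents smoother
        trace, _ = gen_heart_rate(HeartRateModel(gap_rate=0.15), rng, "r", "active", 1)
        ours = hr.impute_gaps(trace)
        uc = sm.tsa.UnobservedComponents(trace.bpm, "llevel")
        res = uc.fit(disp=False)
        theirs = res.smoothed_state[0]
        miss = ~np.isfinite(trace.bpm)
        assert np.max(np.abs(ours.bpm[miss] - theirs[miss])) < 0.5


class TestScaleAndAverage:
    def test_constant_trace_scales_to_one(self):
        sc = hr.scale_baseline(full_length_trace(360.0))
        assert np.allclose(sc.values, 1.0)
        assert sc.baseline_bpm == pytest.approx(360.0)

    def test_pre_stim_mean_is_one(self, rng):
        trace, _ = gen_heart_rate(HeartRateModel(gap_rate=0.0), rng, "r", "active", 1)
        sc = hr.scale_baseline(trace)
        pre = sc.times < sc.stim_window[0]
        assert np.mean(sc.values[pre]) == pytest.approx(1.0, abs=1e-9)

    def test_missing_values_rejected(self):
        bpm = np.full(421, 350.0)
        bpm[5] = np.nan
        with pytest.raises(ValueError, match="missing"):
            hr.scale_baseline(make_trace(bpm))

    def test_average_of_mirrored_traces(self):
        t = np.arange(421.0)
        lo = hr.ScaledTrace(times=t, values=np.full(421, 0.9), baseline_bpm=300.0)
        hi = hr.ScaledTrace(times=t, values=np.full(421, 1.1), baseline_bpm=300.0)
        avg = hr.average_sessions([lo, hi])
        assert np.allclose(avg.values, 1.0)

    def test_single_trace_averages_to_itself(self):
        t = np.arange(421.0)
        one = hr.ScaledTrace(times=t, values=np.linspace(0.9, 1.1, 421), baseline_bpm=300.0)
        assert np.array_equal(hr.average_sessions([one]).values, one.values)

    def test_mismatched_time_bases_rejected(self):
        a = hr.ScaledTrace(times=np.arange(421.0), values=np.ones(421), baseline_bpm=300.0)
        b = hr.ScaledTrace(times=np.arange(400.0), values=np.ones(400), baseline_bpm=300.0)
        with pytest.raises(ValueError, match="time bases"):
            hr.average_sessions([a, b])


class TestAuc:
    def test_constant_trace_inclusive_window_61(self):
        sc = hr.ScaledTrace(times=np.arange(421.0), values=np.ones(421), baseline_bpm=300.0)
        res = hr.auc_window(sc)
        assert res.auc == 61.0
        assert res.n_samples == 61

    def test_zero_trace(self):
        sc = hr.ScaledTrace(times=np.arange(421.0), values=np.zeros(421), baseline_bpm=300.0)
        assert hr.auc_window(sc).auc == 0.0

    def test_linear_ramp_over_window(self):
        t = np.arange(421.0)
        v = np.clip((t - 300.0) / 60.0, 0.0, 1.0)
        assert hr.auc_window(hr.ScaledTrace(times=t, values=v, baseline_bpm=1.0)).auc == pytest.approx(30.5)

    def test_empty_window_rejected(self):
        sc = hr.ScaledTrace(times=np.arange(421.0), values=np.ones(421), baseline_bpm=1.0)
        with pytest.raises(ValueError):
            hr.auc_window(sc, window=(500.0, 560.0))


class TestCompareAuc:
    @staticmethod
    def _results(rng, mean_a, mean_b, n=200):
        # gamma AUCs with the target means, shape 50
        shape = 50.0
        out = []
        for m, cond in ((mean_a, "active"), (mean_b, "control")):
            for i in range(n):
                out.append(hr.AucResult(rat=f"{cond}{i}", condition=cond,
                                        auc=rng.gamma(shape, m / shape),
                                        window=(300, 360), n_samples=61))
        return out

    def test_group_means_recovered(self, rng):
        results = self._results(rng, 66.0, 60.0)
        fit = hr.compare_auc(results)
        assert fit.coefficients[0] == pytest.approx(60.0, rel=0.02)
        assert fit.coefficients[0] + fit.coefficients[1] == pytest.approx(66.0, rel=0.02)

    def test_identical_groups_near_zero_effect(self, rng):
        results = self._results(rng, 61.0, 61.0)
        fit = hr.compare_auc(results)
        assert abs(fit.coefficients[1]) < 1.0

    def test_t_invariant_to_common_rescaling(self, rng):
        results = self._results(rng, 66.0, 60.0, n=50)
        fit1 = hr.compare_auc(results)
        doubled = [hr.AucResult(rat=r.rat, condition=r.condition, auc=2 * r.auc,
                                window=r.window, n_samples=r.n_samples) for r in results]
        fit2 = hr.compare_auc(doubled)
        assert fit2.coefficients[1] == pytest.approx(2 * fit1.coefficients[1], rel=1e-6)
        assert fit2.t_statistics[1] == pytest.approx(fit1.t_statistics[1], abs=1e-6)

    def test_single_condition_rejected(self):
        res = [hr.AucResult(rat="a", condition="active", auc=60.0, window=(300, 360), n_samples=61)] * 4
        with pytest.raises(ValueError, match="condition"):
            hr.compare_auc(res)

    def test_generator_effect_recovered_in_sign(self):
        # active-only 10% stimulation rise: positive condition coefficient
        positives = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cfg = HeartRateModel()
            aucs = []
            for i in range(40):
                cond = "active" if i < 20 else "control"
                tr, _ = gen_heart_rate(cfg, rng, f"r{i}", cond, 1)
                sc = hr.scale_baseline(hr.impute_gaps(tr))
                aucs.append(hr.auc_window(sc))
            fit = hr.compare_auc(aucs)
            positives += fit.coefficients[1] > 0
        assert positives >= 9
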