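import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depotmetry.io import DepositRecord, Site, Substance
from depotmetry.kinetics import (
    ExponentialDecayModel,
    UnderdeterminedFitError,
    VolumeSeries,
    fit_half_life,
    locate_maximum,
    summarize_group,
)
from depotmetry.synthetic import KineticsSimSpec, simulate_volume_series


def exp_series(lam=math.log(2) / 20.0, t_max=4.0, v_max=35.0, v0=20.0, end=24.0, step=2.0):
    t = np.arange(0.0, end + 1e-9, step)
    v = np.where(t <= t_max, v0 + (v_max - v0) * t / t_max, v_max * np.exp(-lam * (t - t_max)))
    return VolumeSeries(t, v)


class TestLocateMaximum:
    def test_interior_peak(self):
        s = VolumeSeries([0, 2, 4, 6, 8], [20, 28, 35, 30, 25])
        assert locate_maximum(s) == (4.0, 35.0)

    def test_monotone_decreasing_peaks_at_baseline(self):
        s = VolumeSeries([0, 2, 4], [30, 20, 10])
        assert locate_maximum(s) == (0.0, 30.0)

    def test_tie_broken_toward_earliest(self):
        s = VolumeSeries([0, 2, 4, 6, 8], [20, 30, 35, 35, 25])
        assert locate_maximum(s)[0] == 4.0


class TestExponentialFit:
    def test_noiseless_half_life_exact_to_three_decimals(self):
        res = fit_half_life(exp_series())
        assert res.t_half == pytest.approx(20.0, abs=5e-4)
        assert res.fit_r2 == pytest.approx(1.0, abs=1e-12)
        assert not res.censored

    def test_noiseless_recovery_is_machine_precision(self):
        res = fit_half_life(exp_series())
        assert res.decay_rate == pytest.approx(math.log(2) / 20.0, rel=1e-12)

    def test_table_fields_are_consistent(self):
        res = fit_half_life(exp_series())
        assert res.v_increase == res.v_max - res.v0
        assert res.v_max_rel == pytest.approx(100.0 * res.v_max / res.v0)
        assert res.t_max in exp_series().times

    def test_fixed_peak_variant_also_exact_on_noiseless_data(self):
        res = fit_half_life(exp_series(), fix_peak=True)
        assert res.t_half == pytest.approx(20.0, rel=1e-9)
        assert res.v_max_hat == pytest.approx(res.v_max, rel=1e-12)

    def test_nonlinear_refinement_matches_on_noiseless_data(self):
        res = fit_half_life(exp_series(), method="nonlinear")
        assert res.t_half == pytest.approx(20.0, rel=1e-6)

    def test_non_decaying_series_is_censored_not_negative(self):
        s = VolumeSeries([0, 2, 4, 6, 8], [20, 21, 22, 23, 24])
        res = fit_half_life(s)
        assert res.censored
        assert math.isinf(res.t_half) and res.t_half > 0

    def test_flat_series_is_censored(self):
        s = VolumeSeries([0, 2, 4, 6], [20, 20, 20, 20])
        res = fit_half_life(s)
        assert res.censored and math.isinf(res.t_half)

    def test_fewer_than_three_post_peak_points_rejected(self):
        s = VolumeSeries([0, 2, 4, 6], [20, 30, 35, 30])  # peak at 4, tail = 2 points
        with pytest.raises(UnderdeterminedFitError):
            fit_half_life(s)

    def test_nonpositive_volumes_rejected_at_construction(self):
        with pytest.raises(ValueError, match="positive"):
            VolumeSeries([0, 2, 4], [20, 0.0, 5])

    def test_time_shift_leaves_decay_untouched(self):
        base = exp_series()
        shifted = VolumeSeries(base.times + 3.0, base.volumes)
        r1, r2 = fit_half_life(base), fit_half_life(shifted)
        assert r2.decay_rate == pytest.approx(r1.decay_rate, rel=1e-12)
        assert r2.t_half == pytest.approx(r1.t_half, rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(k=st.floats(0.01, 100.0))
    def test_volume_scale_invariance(self, k):
        base = exp_series()
        scaled = VolumeSeries(base.times, base.volumes * k)
        r1, r2 = fit_half_life(base), fit_half_life(scaled)
        assert r2.decay_rate == pytest.approx(r1.decay_rate, rel=1e-9)
        assert r2.v_max_rel == pytest.approx(r1.v_max_rel, rel=1e-9)
        assert r2.v_max == pytest.approx(k * r1.v_max, rel=1e-9)
        assert r2.v_increase == pytest.approx(k * r1.v_increase, rel=1e-9)

    def test_model_results_summary_mentions_half_life(self):
        res = ExponentialDecayModel(exp_series()).fit()
        assert "T_1/2" in res.summary()
        assert "20.00" in res.summary()


def _result(substance, t_half, v0=20.0, v_max=35.0, censored=False):
    rec = DepositRecord("m01", Site.A_left_cranial, substance, None)
    lam = math.log(2) / t_half if np.isfinite(t_half) else 0.0
    from depotmetry.kinetics import KineticsResult

    return KineticsResult(
        v0=v0, v_max=v_max, t_max=4.0, v_increase=v_max - v0,
        v_max_rel=100 * v_max / v0, decay_rate=lam, t_half=t_half,
        v_max_hat=v_max, fit_r2=0.99, n_fit_points=8, censored=censored,
        method="loglinear", deposit=rec,
    )


class TestGroupSummary:
    def test_single_result_sd_zero(self):
        df = summarize_group([_result(Substance.PRV, 20.0)])
        assert df.loc["PRV", "t_half_mean"] == 20.0
        assert df.loc["PRV", "t_half_sd"] == 0.0

    def test_two_results_sample_sd(self):
        df = summarize_group([_result(Substance.PRV, 10.0), _result(Substance.PRV, 30.0)])
        assert df.loc["PRV", "t_half_mean"] == pytest.approx(20.0)
        assert df.loc["PRV", "t_half_sd"] == pytest.approx(math.sqrt(200.0), abs=0.01)

    def test_censored_half_lifes_excluded_and_counted(self):
        df = summarize_group([
            _result(Substance.PRV, 10.0),
            _result(Substance.PRV, 30.0),
            _result(Substance.PRV, float("inf"), censored=True),
        ])
        assert df.loc["PRV", "t_half_mean"] == pytest.approx(20.0)
        assert df.loc["PRV", "n_censored"] == 1
        assert df.loc["PRV", "n"] == 3

    def test_mean_of_ratios_not_ratio_of_means(self):
        # two deposits: (v0=10, vmax=30) and (v0=30, vmax=36)
        res = [
            _result(Substance.PRV, 20.0, v0=10.0, v_max=30.0),
            _result(Substance.PRV, 20.0, v0=30.0, v_max=36.0),
        ]
        df = summarize_group(res)
        mean_of_ratios = (300.0 + 120.0) / 2
        ratio_of_means = 100.0 * (30 + 36) / (10 + 30)
        assert df.loc["PRV", "v_max_rel_mean"] == pytest.approx(mean_of_ratios)
        assert mean_of_ratios != pytest.approx(ratio_of_means)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([])


def test_simulated_series_round_trip_recovery():
    spec = KineticsSimSpec(v0=18.0, swell_fraction=0.9, t_max=4.0,
                           decay_rate=math.log(2) / 25.0, noise_cv=0.0)
    res = fit_half_life(simulate_volume_series(spec))
    assert res.t_half == pytest.approx(25.0, rel=1e-9)
    assert res.v_max == pytest.approx(18.0 * 1.9, rel=1e-9)
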