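"""PET, water deficit, MCWD, drought length, binning, response curves."""

import numpy as np
import pandas as pd
import pytest

from canopy2cohorts.drought import (bin_by_mcwd, classify_drought,
                                    cumulative_deficit, drought_length,
                                    fit_response_curve, mcwd,
                                    priestley_taylor_pet, running_mean_12,
                                    shifted_exponential, shifted_weibull,
                                    water_deficit)


class TestPriestleyTaylor:
    def test_zero_available_energy(self):
        assert priestley_taylor_pet(100.0, 100.0, 25.0) == 0.0

    def test_hand_value_at_known_slope_ratio(self):
        # find T where Delta/(Delta+gamma) = 0.7, then lambda*E = 88.2 W m-2
        from scipy.optimize import brentq
        from canopy2cohorts.drought import GAMMA_PSY, saturation_slope
        t = brentq(lambda tt: saturation_slope(tt)
                   / (saturation_slope(tt) + GAMMA_PSY) - 0.7, 0, 50)
        pet = priestley_taylor_pet(100.0, 0.0, t)
        assert pet == pytest.approx(88.2 * 86400 / 2.45e6, rel=1e-3)  # 3.11

    def test_monotone_in_radiation(self):
        rn = np.linspace(0, 300, 50)
        pet = priestley_taylor_pet(rn, 0.0, 26.0)
        assert np.all(np.diff(pet) > 0)


class TestWaterDeficit:
    @pytest.mark.parametrize("p,expected", [(100.0, 0.0), (40.0, 60.0),
                                            (160.0, -60.0)])
    def test_sign_convention(self, p, expected):
        clim = pd.DataFrame({"precip_mm": [p], "pet_mm": [100.0]})
        assert water_deficit(clim)[0] == pytest.approx(expected)


class TestMCWD:
    def test_wet_series_zero_everywhere(self):
        deficit = np.full(24, -50.0)    # always surplus
        out = mcwd(deficit)
        assert np.nanmax(out) == 0.0

    def test_hand_worked_recursion(self):
        # PET 100; P = [120, 40, 30, 120] -> CWD = [0, -60, -130, -110]
        deficit = 100.0 - np.array([120.0, 40.0, 30.0, 120.0])
        cwd = cumulative_deficit(deficit)
        assert cwd == pytest.approx([0.0, -60.0, -130.0, -110.0])
        out = mcwd(deficit, window=4)
        assert out[3] == pytest.approx(130.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            deficit = rng.normal(0, 60, 60)
            out = mcwd(deficit, window=12)
            # independent oracle: direct recursion + window minima
            cwd, acc = [], 0.0
            for d in deficit:
                acc = min(0.0, acc - d)
                cwd.append(acc)
            for m in range(11, 60):
                expect = -min(cwd[m - 11:m + 1])
                assert out[m] == pytest.approx(expect, abs=1e-12)
            assert np.all(np.isnan(out[:11]))

    def test_window_sum_convention(self):
        deficit = np.array([30.0, -10.0, 50.0] + [0.0] * 9)
        out = mcwd(deficit, window=12, convention="window_sum")
        assert out[11] == pytest.approx(80.0)

    def test_short_series_and_window_guards(self):
        with pytest.raises(ValueError):
            mcwd(np.zeros(6), window=12)
        with pytest.raises(ValueError):
            mcwd(np.zeros(24), window=1)


class TestDroughtLength:
    def test_no_drought(self):
        assert drought_length(np.full(12, 10.0))[0] == 0

    def test_longest_run_hand_value(self):
        deficit = np.array([25.0, 30.0, 10.0, 40.0, 50.0, 22.0])
        longest, runs = drought_length(deficit)
        assert longest == 3
        assert list(runs) == [1, 2, 0, 1, 2, 3]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            deficit = rng.normal(20, 30, 60)
            longest, _ = drought_length(deficit)
            best = cur = 0
            for d in deficit:
                cur = cur + 1 if d > 20.0 else 0
                best = max(best, cur)
            assert longest == best

    @pytest.mark.parametrize("months,cls", [(10, "seasonal"), (24, "severe"),
                                            (12, "severe"), (36, "severe"),
                                            (40, "extreme")])
    def test_classification_boundaries(self, months, cls):
        assert classify_drought(months) == cls


class TestBinByMCWD:
    def test_constant_response_constant_medians(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 300, 200)
        bins = bin_by_mcwd(np.full(200, 7.0), m, n_bins=40)
        assert all(b.median == pytest.approx(7.0) for b in bins)

    def test_identity_response_monotone_medians(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 300, 400)
        bins = bin_by_mcwd(m, m, n_bins=40)
        meds = [b.median for b in bins]
        assert meds == sorted(meds)

    def test_bins_partition_and_balance(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(0, 300, 400)
        bins = bin_by_mcwd(m, m, n_bins=40)
        counts = [b.n for b in bins]
        assert sum(counts) == 400
        assert max(counts) - min(counts) <= 1

    def test_too_few_months_errors(self):
        with pytest.raises(ValueError):
            bin_by_mcwd(np.ones(10), np.ones(10), n_bins=40)


class TestResponseCurves:
    def test_weibull_k1_nests_exponential(self):
        x = np.linspace(0, 10, 50)
        ye = shifted_exponential(x, 5.0, 1.0, 2.5)
        yw = shifted_weibull(x, 5.0, 1.0, 2.5, 1.0)
        assert np.max(np.abs(ye - yw)) < 1e-10

    def test_exponential_recovery_and_family_selection(self):
        x = np.linspace(0, 20, 60)
        y = shifted_exponential(x, 8.0, 2.0, 4.0)
        fit = fit_response_curve(x, y)
        assert fit.family == "shifted_exponential"
        assert fit.accepted
        assert fit.params["y_inf"] == pytest.approx(8.0, abs=1e-3)
        assert fit.params["y0"] == pytest.approx(2.0, abs=1e-3)
        assert fit.params["tau"] == pytest.approx(4.0, abs=1e-3)

    def test_weibull_recovery_when_shape_differs(self):
        x = np.linspace(0.1, 20, 80)
        y = shifted_weibull(x, 6.0, 1.0, 5.0, 2.5)
        fit = fit_response_curve(x, y)
        assert fit.family == "shifted_weibull"
        assert fit.params["k"] == pytest.approx(2.5, abs=1e-2)

    def test_pure_noise_rejected(self):
        rejected = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = np.linspace(0, 10, 40)
            y = rng.normal(0, 1, 40)
            fit = fit_response_curve(x, y, seed=seed)
            rejected += not fit.accepted
        assert rejected >= 29   # >= 95%

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="8 points"):
            fit_response_curve([0, 1, 2], [1, 2, 3])


def test_running_mean_12_window():
    s = np.arange(24.0)
    rm = running_mean_12(s)
    assert np.all(np.isnan(rm[:11]))
    assert rm[11] == pytest.approx(np.mean(np.arange(12.0)))
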