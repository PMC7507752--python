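"""Synthetic stand, lidar and climate generators."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from canopy2cohorts import synthetic
from canopy2cohorts.allometry import basal_area_cm2
from canopy2cohorts.synthetic import (SyntheticStandConfig, generate_climate,
                                      generate_stand, simulate_point_cloud)


class TestGenerateStand:
    def test_zero_density_gives_empty_stand(self):
        cfg = SyntheticStandConfig(stem_density=0.0)
        stems, truth = generate_stand(cfg)
        assert len(stems) == 0
        assert truth.agb == truth.basal_area == truth.lai == 0.0

    def test_single_stem_basal_area_hand_value(self):
        # density 4/ha on 2500 m2 -> one stem; override DBH to 30 cm
        cfg = SyntheticStandConfig(stem_density=4.0, rng_seed=1)
        stems, _ = generate_stand(cfg)
        assert len(stems) == 1
        stems.loc[0, "dbh_cm"] = 30.0
        from canopy2cohorts.synthetic import _stand_truth
        from canopy2cohorts.allometry import default_allometry
        truth = _stand_truth(stems, 2500.0, default_allometry())
        assert truth.basal_area == pytest.approx(
            math.pi * 15.0**2 / 2500.0, rel=1e-12)

    def test_seeded_determinism(self):
        cfg = SyntheticStandConfig(rng_seed=42)
        s1, t1 = generate_stand(cfg)
        s2, t2 = generate_stand(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        assert t1 == t2

    def test_truth_equals_per_stem_sums(self, allom):
        cfg = SyntheticStandConfig(stem_density=400.0, rng_seed=3)
        stems, truth = generate_stand(cfg, allom)
        ba = sum(basal_area_cm2(d) for d in stems.dbh_cm) / cfg.plot_area
        assert truth.basal_area == pytest.approx(ba, rel=1e-12)
        assert truth.stem_density == pytest.approx(
            len(stems) / cfg.plot_area * 1e4)

    def test_dbh_floor_respected(self):
        cfg = SyntheticStandConfig(stem_density=600.0, rng_seed=9)
        stems, _ = generate_stand(cfg)
        assert (stems.dbh_cm >= 10.0).all()

    def test_bad_mixture_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticStandConfig(pft_mixture={"early": 0.5, "mid": 0.4})


class TestSimulatePointCloud:
    def test_bare_ground_all_returns_at_zero(self):
        stems = pd.DataFrame(columns=["x", "y", "dbh_cm", "height_m",
                                      "crown_radius_m", "crown_depth_m",
                                      "pft"])
        cloud = simulate_point_cloud(stems, 2500.0, 4.0, rng_seed=0)
        assert cloud.is_ground.all()
        assert (cloud.z == 0.0).all()

    def test_opaque_slab_intercepts_all_first_returns(self, allom):
        # a giant effectively opaque crown spanning the plot at 20-21 m
        stems = pd.DataFrame([{
            "x": 25.0, "y": 25.0, "dbh_cm": 50.0, "height_m": 21.0,
            "crown_radius_m": 100.0, "crown_depth_m": 1.0, "pft": "mid",
        }])
        # blow up leaf area via a huge k so interception prob ~ 1
        cloud = simulate_point_cloud(stems, 2500.0, 2.0, rng_seed=0, k=1e6)
        first = cloud[cloud.return_number == 1]
        assert not first.empty
        assert ((first.z >= 20.0) & (first.z <= 21.0)).all()

    def test_ground_fraction_matches_beer_lambert(self):
        """Monte-Carlo gap fraction converges to exp(-k*LAD*dz)."""
        k, dz = 0.5, 1.0
        # one uniform crown layer over the whole plot in a single bin
        leaf_area = 2.0 * 2500.0   # LAD = 2.0 in the 20-21 m bin
        stems = pd.DataFrame([{
            "x": 25.0, "y": 25.0, "dbh_cm": 50.0, "height_m": 21.0,
            "crown_radius_m": 100.0, "crown_depth_m": 1.0, "pft": "mid",
        }])
        lad = leaf_area / (math.pi * 100.0**2 * 1.0)
        p_ground = math.exp(-k * lad * dz)
        cloud = simulate_point_cloud(stems, 2500.0, 40.0, rng_seed=1, k=k,
                                     allom=_fixed_leaf_allom(leaf_area))
        n = cloud.groupby(["x", "y"]).ngroups  # pulses
        n_ground = int(cloud.is_ground.sum())
        # two-sided binomial test at alpha = 0.01
        res = stats.binomtest(n_ground, n, p_ground)
        assert res.pvalue > 0.01

    def test_return_density_guarantee(self, small_scene):
        """At least the configured pulses land in >= 99.5% of 1 m2 cells."""
        cloud = small_scene.point_cloud
        gx = np.floor(cloud.x).astype(int)
        gy = np.floor(cloud.y).astype(int)
        counts = pd.DataFrame({"gx": gx, "gy": gy}).groupby(
            ["gx", "gy"]).size()
        frac_ok = (counts >= 4).sum() / (50 * 50)
        assert frac_ok >= 0.995

    def test_negative_density_errors(self):
        stems = pd.DataFrame()
        with pytest.raises(ValueError, match="pulse_density"):
            simulate_point_cloud(stems, 2500.0, -1.0)

    def test_seeded_reproducibility(self, small_scene):
        cfg = small_scene.config
        again = synthetic.generate_scene(cfg, pulse_density=4.0)
        pd.testing.assert_frame_equal(small_scene.point_cloud,
                                      again.point_cloud)


def _fixed_leaf_allom(leaf_area):
    """Allometry whose leaf-area law returns a constant (exp 0)."""
    from canopy2cohorts.allometry import AllometrySet, PFTAllometry
    return AllometrySet(pfts={"mid": PFTAllometry(
        h_max=40.0, h_a=0.05, h_b=1.0, leaf_l0=leaf_area, leaf_exp=0.0,
        agb_c0=0.0673, agb_c1=0.976, wood_density=0.6)})


class TestGenerateClimate:
    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError, match="12 months"):
            generate_climate(6)

    def test_noise_free_flat_series_has_no_deficit(self):
        clim = generate_climate(24, mean_precip_peak=200.0, dry_trough=150.0,
                                dry_season_months=0, pet_mean=100.0,
                                pet_amplitude=0.0, noise_sigma=0.0)
        deficit = clim.pet_mm - clim.precip_mm
        assert (deficit <= 0).all()

    def test_dry_season_month_count_exact(self):
        for d in (3, 5, 7):
            clim = generate_climate(12, dry_season_months=d, noise_sigma=0.0)
            assert int((clim.precip_mean_mm < 100.0).sum()) == d

    def test_non_negative_and_reproducible(self):
        c1 = generate_climate(60, rng_seed=5)
        c2 = generate_climate(60, rng_seed=5)
        pd.testing.assert_frame_equal(c1, c2)
        assert (c1.precip_mm >= 0).all() and (c1.pet_mm >= 0).all()
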