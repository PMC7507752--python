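"""KS matching, layer splitting, cohort construction, scaling, ensembles."""

import numpy as np
import pytest

from canopy2cohorts.allometry import (PlotProperties, integrate_properties,
                                      leaf_area_m2)
from canopy2cohorts.cohorts import (CohortLayer, TrainingLibrary,
                                    TrainingPlot, build_ensembles,
                                    fit_scaling_factor, global_scaling,
                                    ks_statistic, layers_to_cohorts,
                                    match_profile, profile_to_stack,
                                    split_layers)


class TestKSStatistic:
    def test_identical_profiles_zero(self, profile_factory):
        p = profile_factory([0.1, 0.5, 0.3])
        assert ks_statistic(p, p) == 0.0

    def test_disjoint_mass_gives_one(self, profile_factory):
        a = profile_factory([1.0, 0.0])
        b = profile_factory([0.0, 1.0])
        assert ks_statistic(a, b) == pytest.approx(1.0)

    def test_two_bin_hand_value(self, profile_factory):
        a = profile_factory([0.5, 0.5])
        b = profile_factory([1.0, 0.0])
        assert ks_statistic(a, b) == pytest.approx(0.5)

    def test_zero_profile_errors(self, profile_factory):
        with pytest.raises(ValueError, match="zero total"):
            ks_statistic(profile_factory([0.0, 0.0]),
                         profile_factory([1.0, 0.0]))

    def test_symmetry(self, profile_factory):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = profile_factory(rng.random(30))
            b = profile_factory(rng.random(30))
            assert ks_statistic(a, b) == pytest.approx(ks_statistic(b, a))


class TestMatchProfile:
    def _library(self, profiles):
        return TrainingLibrary([
            TrainingPlot(plot_id=f"p{i:03d}", profile=p,
                         pft_mixture={"mid": 1.0})
            for i, p in enumerate(profiles)
        ])

    def test_self_match(self, profile_factory):
        profs = [profile_factory([1, 2, 1]), profile_factory([0, 1, 3])]
        lib = self._library(profs)
        m = match_profile(profs[1], lib)
        assert m.plot_id == "p001" and m.ks_statistic == 0.0

    def test_argmin_selection(self, profile_factory):
        query = profile_factory([1.0, 1.0])
        near = profile_factory([1.1, 0.9])
        far = profile_factory([5.0, 0.1])
        m = match_profile(query, self._library([far, near]))
        assert m.plot_id == "p001"

    def test_matches_brute_force_on_random_libraries(self, profile_factory):
        rng = np.random.default_rng(5)
        profs = [profile_factory(rng.random(25)) for _ in range(50)]
        lib = self._library(profs)
        for _ in range(50):
            q = profile_factory(rng.random(25))
            ds = [ks_statistic(q, p.profile) for p in lib.plots]
            expected = lib.plots[int(np.argmin(ds))].plot_id
            assert match_profile(q, lib).plot_id == expected

    def test_empty_library_errors(self, profile_factory):
        with pytest.raises(ValueError, match="empty"):
            match_profile(profile_factory([1.0]), TrainingLibrary([]))


class TestSplitLayers:
    def test_unimodal_single_layer(self, profile_factory):
        lad = np.concatenate([np.zeros(5), [1, 2, 3, 2, 1], np.zeros(5)])
        layers = split_layers(profile_factory(lad))
        assert len(layers) == 1
        assert layers[0].bottom == 5 and layers[0].top == 9
        assert layers[0].peak_height == pytest.approx(7.5)

    def test_two_peaks_boundary_at_valley(self, profile_factory):
        lad = np.zeros(20)
        lad[3:8] = [1, 2, 3, 2, 1]
        lad[8:13] = [0.5, 0.5, 0.5, 2.5, 1]   # valley at bin 8-10, peak at 11
        layers = split_layers(profile_factory(lad))
        assert len(layers) == 2
        assert layers[0].top == 7 and layers[1].bottom == 8

    def test_leaf_area_conservation(self, profile_factory):
        rng = np.random.default_rng(9)
        for _ in range(20):
            lad = rng.random(40) * (rng.random(40) > 0.3)
            prof = profile_factory(lad)
            layers = split_layers(prof)
            assert sum(l.leaf_area for l in layers) == pytest.approx(
                lad.sum(), abs=1e-9)

    def test_all_zero_profile_empty(self, profile_factory):
        assert split_layers(profile_factory(np.zeros(10))) == []

    def test_weak_peak_merged_by_prominence(self, profile_factory):
        lad = np.zeros(15)
        lad[2:7] = [1, 2, 5, 2, 1]
        lad[7:10] = [0.98, 1.0, 0.9]     # bump prominence 0.02 < 5% of 5
        layers = split_layers(profile_factory(lad), prominence_fraction=0.05)
        assert len(layers) == 1

    def test_max_depth_subdivision_conserves_area(self, profile_factory):
        lad = np.concatenate([np.zeros(3), np.linspace(1, 3, 20)[::-1],
                              np.zeros(4)])
        prof = profile_factory(lad)
        deep = split_layers(prof)
        shallow = split_layers(prof, max_layer_depth=5.0)
        assert len(deep) == 1 and len(shallow) >= 4
        assert sum(l.leaf_area for l in shallow) == pytest.approx(
            lad.sum(), abs=1e-9)


class TestLayersToCohorts:
    def test_single_layer_single_pft_conservation(self, allom):
        layer = CohortLayer(bottom=10, top=14, peak_bin=12,
                            peak_height=12.5, leaf_area=500.0)
        stack = layers_to_cohorts([layer], {"mid": 1.0}, 2500.0, allom)
        assert len(stack) == 1
        c = stack.cohorts[0]
        n_ind = c.density * 2500.0
        assert n_ind * leaf_area_m2(c.dbh, "mid", allom) == pytest.approx(
            500.0, rel=1e-9)

    def test_even_mixture_splits_leaf_area(self, allom):
        layer = CohortLayer(bottom=10, top=14, peak_bin=12,
                            peak_height=12.5, leaf_area=400.0)
        stack = layers_to_cohorts([layer], {"mid": 0.5, "late": 0.5},
                                  2500.0, allom)
        assert len(stack) == 2
        las = sorted(c.lai * 2500.0 for c in stack)
        assert las == pytest.approx([200.0, 200.0])

    def test_empty_layers_empty_stack(self, allom):
        assert len(layers_to_cohorts([], {"mid": 1.0}, 100.0, allom)) == 0

    def test_grass_mass_reassigned_above_two_metres(self, allom):
        layer = CohortLayer(bottom=10, top=12, peak_bin=11,
                            peak_height=11.5, leaf_area=100.0)
        stack = layers_to_cohorts([layer], {"grass": 0.4, "mid": 0.6},
                                  2500.0, allom)
        assert all(c.pft != "grass" for c in stack)
        assert stack.lai * 2500.0 == pytest.approx(100.0)

    def test_grass_keeps_mass_below_two_metres(self, allom):
        layer = CohortLayer(bottom=0, top=1, peak_bin=0,
                            peak_height=0.5, leaf_area=50.0)
        stack = layers_to_cohorts([layer], {"grass": 0.5, "mid": 0.5},
                                  2500.0, allom)
        assert {c.pft for c in stack} == {"grass", "mid"}

    def test_infeasible_height_reassigned_to_tallest(self, allom):
        # 30 m layer exceeds 'early' h_max (28 m): share goes to 'late'
        layer = CohortLayer(bottom=29, top=31, peak_bin=30,
                            peak_height=30.5, leaf_area=100.0)
        stack = layers_to_cohorts([layer], {"early": 0.5, "late": 0.5},
                                  2500.0, allom)
        assert {c.pft for c in stack} == {"late"}
        assert stack.lai * 2500.0 == pytest.approx(100.0)


class TestFitScalingFactor:
    def _profile(self, profile_factory):
        lad = np.zeros(40)
        lad[8:20] = [0.05, 0.1, 0.2, 0.35, 0.4, 0.38, 0.3, 0.25, 0.18,
                     0.1, 0.05, 0.02]
        return profile_factory(lad)

    def test_fixed_point_returns_unity(self, profile_factory, allom):
        prof = self._profile(profile_factory)
        mixture = {"mid": 0.6, "late": 0.4}
        stack = profile_to_stack(prof, mixture, 2500.0, allom)
        target = integrate_properties(stack, 2500.0, allom)
        res = fit_scaling_factor(prof, mixture, target, 2500.0, allom=allom)
        assert res.factor == pytest.approx(1.0, abs=1e-3)
        assert res.objective < 1e-8

    def test_lai_only_objective_closed_form(self, profile_factory, allom):
        prof = self._profile(profile_factory)
        mixture = {"mid": 1.0}
        lai0 = prof.lai
        target = PlotProperties(agb=1.0, basal_area=1.0, stem_density=1.0,
                                lai=lai0 / 2.0)
        res = fit_scaling_factor(prof, mixture, target, 2500.0, allom=allom,
                                 properties=("lai",))
        assert res.factor == pytest.approx(0.5, abs=1e-3)

    def test_matches_grid_search_oracle(self, profile_factory, allom):
        rng = np.random.default_rng(3)
        bounds = (0.05, 20.0)
        for _ in range(5):
            lad = np.zeros(40)
            sl = slice(5, 5 + rng.integers(8, 25))
            lad[sl] = rng.random(sl.stop - sl.start) + 0.05
            prof = profile_factory(lad)
            mixture = {"mid": 0.7, "late": 0.3}
            target = PlotProperties(
                agb=rng.uniform(5, 30), basal_area=rng.uniform(10, 40),
                stem_density=rng.uniform(300, 700), lai=rng.uniform(2, 8))

            def objective(s):
                stack = profile_to_stack(prof.rescaled(s), mixture, 2500.0,
                                         allom)
                props = integrate_properties(stack, 2500.0, allom)
                return sum(((getattr(props, k) - getattr(target, k))
                            / getattr(target, k))**2
                           for k in ("agb", "basal_area", "stem_density",
                                     "lai"))

            grid = np.arange(bounds[0], bounds[1] + 1e-9, 1e-3)
            vals = [objective(s) for s in grid]
            s_grid = grid[int(np.argmin(vals))]
            res = fit_scaling_factor(prof, mixture, target, 2500.0,
                                     bounds=bounds, allom=allom)
            assert res.factor == pytest.approx(s_grid, abs=2e-3)

    def test_nonpositive_target_errors(self, profile_factory, allom):
        prof = self._profile(profile_factory)
        target = PlotProperties(agb=0.0, basal_area=1.0, stem_density=1.0,
                                lai=1.0)
        with pytest.raises(ValueError, match="positive"):
            fit_scaling_factor(prof, {"mid": 1.0}, target, 2500.0,
                               allom=allom)


class TestGlobalScaling:
    @pytest.mark.parametrize("factors,expected", [
        ([1.0, 1.0, 1.0], 1.0),
        ([0.5, 1.0, 3.0], 1.0),
        ([1.0, 2.0, 3.0, 4.0], 2.5),
    ])
    def test_median_conventions(self, factors, expected):
        assert global_scaling(factors) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            global_scaling([])


class TestBuildEnsembles:
    def _stack(self, cid, region, dist):
        from canopy2cohorts.allometry import CohortStack
        return CohortStack([], column_id=cid, region=region,
                           disturbance=dist)

    def test_equal_weights_sum_to_one(self):
        stacks = [self._stack(f"c{i}", "PRG", "INT") for i in range(10)]
        (ens,) = build_ensembles(stacks)
        assert np.allclose(ens.weights, 0.1)
        assert ens.weights.sum() == pytest.approx(1.0)

    def test_partition_no_stack_in_two_groups(self):
        stacks = ([self._stack(f"a{i}", "PRG", "INT") for i in range(3)]
                  + [self._stack(f"b{i}", "PRG", "BN1") for i in range(2)]
                  + [self._stack("c0", "GYF", "INT")])
        ensembles = build_ensembles(stacks)
        assert len(ensembles) == 3
        ids = [s.column_id for e in ensembles for s in e.members]
        assert len(ids) == len(set(ids)) == 6
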