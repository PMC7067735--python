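import numpy as np
import pytest

from habfish import (
    HabitatGenConfig,
    RasterGrid,
    generate_habitat_map,
    generate_landscape,
    generate_monitoring,
)
from habfish.synthetic import ConfigurationError, scenario_prevalence
from scipy import ndimage


class TestLandscape:
    def test_deterministic_for_fixed_seed(self, gen_config):
        a = generate_landscape(gen_config)
        b = generate_landscape(HabitatGenConfig(seed=gen_config.seed))
        np.testing.assert_array_equal(a.water_mask.values, b.water_mask.values)
        np.testing.assert_array_equal(a.depth.values, b.depth.values)
        np.testing.assert_array_equal(a.secchi_base.values, b.secchi_base.values)

    def test_invariants(self, landscape):
        water = landscape.water
        assert 0.5 <= water.mean() <= 0.95
        assert np.all(landscape.depth.values[water] > 0)
        assert np.all(landscape.secchi_base.values[water] > 0)
        # land is nodata in depth and secchi
        assert np.all(np.isnan(landscape.depth.values[~water]))
        assert np.all(np.isnan(landscape.secchi_base.values[~water]))
        # connected land margin along the west edge
        assert np.all(landscape.water_mask.values[:, 0] == 0)

    def test_depth_increases_with_distance_from_land(self, landscape):
        water = landscape.water
        dist = ndimage.distance_transform_edt(water)
        r = np.corrcoef(dist[water], landscape.depth.values[water])[0, 1]
        assert r > 0

    def test_too_small_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            HabitatGenConfig(grid_size=8)


class TestHabitatMaps:
    def test_habitat_binary_and_confined_to_water(self, landscape, gen_config):
        for species in ("perch", "pikeperch"):
            g = generate_habitat_map(landscape, species, 0, "gam", gen_config)
            water = landscape.water
            assert set(np.unique(g.values[water])) <= {0.0, 1.0}
            assert np.all(np.isnan(g.values[~water]))

    @pytest.mark.parametrize(
        "species,direction", [("perch", 1), ("pikeperch", -1)]
    )
    def test_prevalence_monotone_in_scenario(self, landscape, gen_config, species, direction):
        """Prevalence follows the sign of the Secchi response across all
        seven scenario levels, for every technique."""
        for technique in gen_config.techniques:
            prevalences = []
            for level in sorted(gen_config.scenario_levels):
                g = generate_habitat_map(landscape, species, level, technique, gen_config)
                prevalences.append(np.nanmean(g.values))
            diffs = direction * np.diff(prevalences)
            assert np.all(diffs > 0)

    def test_prevalence_matches_logistic_target(self, landscape, gen_config):
        water_n = landscape.water.sum()
        for level in (-10, 0, 48):
            g = generate_habitat_map(landscape, "perch", level, "rf", gen_config)
            target = scenario_prevalence(
                gen_config.base_prevalence["perch"],
                gen_config.secchi_response["perch"],
                level,
            )
            assert np.nanmean(g.values) == pytest.approx(target, abs=2 / water_n)

    def test_zero_response_gives_equal_prevalence(self, landscape):
        cfg = HabitatGenConfig(
            seed=3,
            base_prevalence={"perch": 0.3, "pikeperch": 0.15, "flatfish": 0.25},
            secchi_response={"perch": 2.0, "pikeperch": -3.0, "flatfish": 0.0},
        )
        maps = [
            generate_habitat_map(landscape, "flatfish", lv, "gam", cfg)
            for lv in (0, 48)
        ]
        assert np.nanmean(maps[0].values) == pytest.approx(np.nanmean(maps[1].values))

    def test_habitat_spatially_autocorrelated(self, landscape, gen_config):
        """Join-count style check: habitat cells have habitat neighbours far
        more often than the random (prevalence) expectation."""
        g = generate_habitat_map(landscape, "perch", 0, "gam", gen_config)
        hab = np.nan_to_num(g.values, nan=0.0)
        neighbour_sum = (
            np.roll(hab, 1, 0) + np.roll(hab, -1, 0) + np.roll(hab, 1, 1) + np.roll(hab, -1, 1)
        )
        p_hab = np.nanmean(g.values)
        same_neighbour_rate = neighbour_sum[hab == 1].mean() / 4
        assert same_neighbour_rate > 1.5 * p_hab

    def test_techniques_are_correlated_variants(self, landscape, gen_config):
        water = landscape.water
        maps = [
            generate_habitat_map(landscape, "perch", 0, t, gen_config).values[water]
            for t in gen_config.techniques
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(maps[i], maps[j])[0, 1]
                assert r > 0.5  # broadly agreeing...
                assert not np.array_equal(maps[i], maps[j])  # ...but not identical

    def test_unknown_labels_rejected(self, landscape, gen_config):
        with pytest.raises(ConfigurationError):
            generate_habitat_map(landscape, "cod", 0, "gam", gen_config)
        with pytest.raises(ConfigurationError):
            generate_habitat_map(landscape, "perch", 0, "kriging", gen_config)
        with pytest.raises(ConfigurationError):
            generate_habitat_map(landscape, "perch", 17, "gam", gen_config)

    def test_response_sign_constraints(self):
        with pytest.raises(ConfigurationError):
            HabitatGenConfig(secchi_response={"perch": -1.0, "pikeperch": -3.0})
        with pytest.raises(ConfigurationError):
            HabitatGenConfig(secchi_response={"perch": 2.0, "pikeperch": 0.5})
        with pytest.raises(ConfigurationError):
            HabitatGenConfig(base_prevalence={"perch": 1.5, "pikeperch": 0.15})


class TestMonitoring:
    @pytest.fixture()
    def cpue(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(1, 9, (32, 32))
        vals[:, :6] = np.nan  # land strip
        return RasterGrid(vals, 250.0)

    def test_noiseless_observations_equal_map(self, cpue):
        df = generate_monitoring(cpue, n_sites=20, noise_sd=0.0, seed=1)
        pred = cpue.values[df["row"], df["col"]]
        np.testing.assert_allclose(df["observed_cpue"], pred)

    def test_deterministic_and_on_water(self, cpue):
        a = generate_monitoring(cpue, 15, 0.5, seed=9)
        b = generate_monitoring(cpue, 15, 0.5, seed=9)
        assert a.equals(b)
        assert not np.isnan(cpue.values[a["row"], a["col"]]).any()
        assert len(a) == 15 and a["site_id"].is_unique

    def test_truncation_at_zero(self):
        cpue = RasterGrid(np.full((8, 8), 0.01), 100.0)
        df = generate_monitoring(cpue, 30, noise_sd=5.0, seed=2)
        assert (df["observed_cpue"] >= 0).all()

    def test_errors(self, cpue):
        with pytest.raises(ConfigurationError):
            generate_monitoring(cpue, 2, 0.1, seed=0)
        with pytest.raises(ConfigurationError):
            generate_monitoring(cpue, 10_000, 0.1, seed=0)
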