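import numpy as np
import pandas as pd
import pytest

from habfish import (
    EnsembleSummary,
    RasterGrid,
    area_summary,
    relative_change,
    summary_table,
    technique_ensemble,
)
from habfish.ensemble import area_mean
from habfish.raster import RasterError


def grids(*arrays, cell=250.0):
    return [RasterGrid(np.asarray(a, dtype=float), cell) for a in arrays]


class TestTechniqueEnsemble:
    def test_closed_form_for_1_2_3(self):
        maps = grids(np.full((4, 4), 1.0), np.full((4, 4), 2.0), np.full((4, 4), 3.0))
        mean, se = technique_ensemble(maps)
        np.testing.assert_allclose(mean.values, 2.0)
        np.testing.assert_allclose(se.values, 1 / np.sqrt(3))

    def test_identical_maps_zero_se(self):
        maps = grids(*([np.random.default_rng(0).random((5, 5))] * 3))
        _, se = technique_ensemble(maps)
        np.testing.assert_allclose(se.values, 0.0, atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        arrays = [rng.random((6, 6)) for _ in range(3)]
        m1, s1 = technique_ensemble(grids(*arrays))
        m2, s2 = technique_ensemble(grids(*arrays[::-1]))
        np.testing.assert_allclose(m1.values, m2.values, rtol=1e-12)
        np.testing.assert_allclose(s1.values, s2.values, rtol=1e-12, atol=1e-15)

    def test_nodata_propagates(self):
        a = np.ones((2, 2))
        b = np.ones((2, 2))
        b[0, 0] = np.nan
        mean, se = technique_ensemble(grids(a, b, a))
        assert np.isnan(mean.values[0, 0]) and np.isnan(se.values[0, 0])
        assert np.isfinite(mean.values[1, 1])

    def test_sd_mode(self):
        maps = grids(np.full((2, 2), 1.0), np.full((2, 2), 2.0), np.full((2, 2), 3.0))
        _, sd = technique_ensemble(maps, use_se=False)
        np.testing.assert_allclose(sd.values, 1.0)

    def test_fewer_than_two_maps_rejected(self):
        with pytest.raises(ValueError):
            technique_ensemble(grids(np.ones((2, 2))))


class TestAreaSummary:
    def test_uniform_field(self, species_params):
        sp = species_params["pikeperch"]
        v = 0.4
        members = grids(*[np.full((10, 10), v)] * 3)
        mean, _ = technique_ensemble(members)
        s = area_summary(mean, members, sp, scenario=0)
        assert s.mean_density == pytest.approx(v)
        assert s.se_density == pytest.approx(0.0)
        assert s.area_ha == pytest.approx(100 * 6.25)
        assert s.total_biomass == pytest.approx(v * 100 * 6.25)

    def test_mean_matches_bruteforce_over_valid_cells(self, species_params):
        rng = np.random.default_rng(3)
        arrays = [rng.random((12, 12)) for _ in range(3)]
        for a in arrays:
            a[:3, :3] = np.nan
        members = grids(*arrays)
        mean, _ = technique_ensemble(members)
        s = area_summary(mean, members, species_params["perch"], scenario=0)
        acc, cnt = 0.0, 0
        for i in range(12):
            for j in range(12):
                v = mean.values[i, j]
                if not np.isnan(v):
                    acc += v
                    cnt += 1
        assert s.mean_density == pytest.approx(acc / cnt)
        assert s.n_valid_cells == cnt

    def test_halving_cell_size_keeps_intensive_and_extensive_measures(self, species_params):
        sp = species_params["perch"]
        coarse = np.full((10, 10), 2.5)
        fine = np.full((20, 20), 2.5)
        s1 = area_summary(
            *[grids(coarse)[0], grids(coarse, coarse, coarse)], sp, 0
        )
        s2 = area_summary(
            *[grids(fine, cell=125.0)[0], grids(fine, fine, fine, cell=125.0)], sp, 0
        )
        assert s1.mean_density == pytest.approx(s2.mean_density)
        assert s1.total_biomass == pytest.approx(s2.total_biomass)

    def test_all_nodata_rejected(self, species_params):
        nanmap = np.full((4, 4), np.nan)
        members = grids(nanmap, nanmap, nanmap)
        with pytest.raises(RasterError):
            area_summary(members[0], members, species_params["perch"], 0)

    def test_area_mean_requires_valid_cells(self):
        with pytest.raises(RasterError):
            area_mean(RasterGrid(np.full((3, 3), np.nan), 250.0))


class TestRelativeChange:
    def _summary(self, species, scenario, mean):
        return EnsembleSummary(species, scenario, mean, 0.0, 0.0, 1, 1.0)

    def test_identity_and_arithmetic(self):
        base = self._summary("perch", 0, 10.0)
        assert relative_change(self._summary("perch", 11, 10.0), base) == 0.0
        assert relative_change(self._summary("perch", 11, 11.3), base) == pytest.approx(13.0)
        assert relative_change(self._summary("perch", 48, 4.1), base) == pytest.approx(-59.0)

    def test_species_and_baseline_guards(self):
        base = self._summary("perch", 0, 10.0)
        with pytest.raises(ValueError):
            relative_change(self._summary("pikeperch", 11, 5.0), base)
        with pytest.raises(ValueError):
            relative_change(base, self._summary("perch", 11, 5.0))
        zero = self._summary("perch", 0, 0.0)
        with pytest.raises(ZeroDivisionError):
            relative_change(self._summary("perch", 11, 5.0), zero)

    def test_summary_table_shape_and_changes(self):
        rows = [
            self._summary("perch", 0, 10.0),
            self._summary("perch", 11, 11.0),
            self._summary("pikeperch", 0, 1.0),
            self._summary("pikeperch", 11, 0.9),
        ]
        df = summary_table(rows)
        assert list(df.columns) == [
            "species", "scenario", "mean_kg_ha", "se_kg_ha",
            "total_kg", "area_ha", "rel_change_pct",
        ]
        assert len(df) == 4
        perch11 = df[(df.species == "perch") & (df.scenario == 11)]
        assert perch11["rel_change_pct"].iloc[0] == pytest.approx(10.0)
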