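"""Soil classes, grid features, response/risk maps, scenarios, uncertainty."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanophyto.forest import ForestSpec
from nanophyto.model import PlantResponseForest
from nanophyto.projection import (
    ScenarioSpec,
    apply_scenario,
    build_grid_features,
    classify_soil,
    oxidative_risk_levels,
    uncertainty_map,
)
from nanophyto.schema import OXIDATIVE_LABELS
from nanophyto.simulate import EffectSpec, generate_experiment_table, generate_raster_stack


class TestClassifySoil:
    @pytest.mark.parametrize(
        "ph, expected",
        [(6.0, "acid"), (6.49, "acid"), (6.5, "neutral"), (7.0, "neutral"),
         (7.5, "neutral"), (7.51, "alkaline"), (8.0, "alkaline")],
    )
    def test_boundary_semantics(self, ph, expected):
        assert classify_soil(ph) == expected

    @given(ph=st.floats(0.0, 14.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_partitions_the_ph_scale(self, ph):
        assert classify_soil(ph) in {"acid", "neutral", "alkaline"}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_soil(-0.1)
        with pytest.raises(ValueError):
            classify_soil(14.5)


@pytest.fixture(scope="module")
def stack():
    return generate_raster_stack(18, 24, seed=42)


@pytest.fixture(scope="module")
def stress_results():
    """Forests for the four oxidative indicators plus growth, fitted on a
    table with temperature- and dose-driven responses."""
    spec = EffectSpec(
        n=300,
        effects={"total_dose": 25.0, "night_temperature": -15.0,
                 "daytime_temperature": 8.0},
        noise_sd=5.0,
        seed=77,
        label_set=("length",) + OXIDATIVE_LABELS,
    )
    table = generate_experiment_table(spec)
    fs = ForestSpec(ntree=40, seed=0)
    return {
        lb: PlantResponseForest.from_dataframe(table, lb, fs).fit()
        for lb in ("length",) + OXIDATIVE_LABELS
    }


class TestGridFeatures:
    def test_record_count_matches_valid_crop_cells(self, stack):
        grid = build_grid_features(stack, "wheat", "ZnO", dose=50.0)
        expected = int((stack.mask & (stack.layer("crop_mask") > 0)).sum())
        assert grid.n_cells == expected

    def test_identical_cells_give_identical_records(self, stack):
        grid = build_grid_features(stack, "bean", "Fe2O3")
        env_cols = ["daytime_temperature", "night_temperature",
                    "illumination_intensity", "relative_humidity"]
        rec = grid.records
        dupes = rec[env_cols].round(9).duplicated(keep=False)
        if dupes.any():
            groups = rec[dupes].groupby(env_cols, sort=False)
            for _, g in groups:
                assert (g.nunique() <= 1).all()

    def test_all_masked_stack_warns_and_is_empty(self, stack):
        empty = stack.with_layers(crop_mask=np.zeros(stack.shape))
        with pytest.warns(UserWarning, match="no valid crop cells"):
            grid = build_grid_features(empty, "maize", "ZnO")
        assert grid.n_cells == 0

    def test_missing_layer_rejected(self, stack):
        broken = type(stack)(
            {k: v for k, v in stack.layers.items() if k != "soil_pH"},
            stack.geo, stack.mask,
        )
        with pytest.raises(ValueError, match="soil_pH"):
            build_grid_features(broken, "wheat", "ZnO")

    def test_soil_ph_mapped_to_culture(self, stack):
        grid = build_grid_features(stack, "wheat", "ZnO")
        cultures = set(grid.records["plant_culture"])
        assert cultures <= {"acidic soil", "neutral soil", "alkaline soil"}


class TestProjectResponse:
    def test_mask_preserved_and_values_in_range(self, stack, stress_results):
        rmap = stress_results["H2O2"].project(stack, "wheat", "ZnO", dose=50.0,
                                              measured_tissue="leaf")
        valid = rmap.mask
        assert np.isnan(rmap.values[~valid]).all()
        vals = rmap.values[valid]
        assert np.isfinite(vals).all()
        assert (vals >= -1).all() and (vals < 1).all()

    def test_dose_changes_the_map(self, stack, stress_results):
        res = stress_results["H2O2"]
        lo = res.project(stack, "wheat", "ZnO", dose=0.0, measured_tissue="leaf")
        hi = res.project(stack, "wheat", "ZnO", dose=50.0, measured_tissue="leaf")
        diff = np.nanmean(np.abs(hi.values - lo.values))
        assert diff > 0

    def test_projection_is_deterministic(self, stack, stress_results):
        res = stress_results["length"]
        a = res.project(stack, "bean", "Fe2O3")
        b = res.project(stack, "bean", "Fe2O3")
        np.testing.assert_array_equal(a.values, b.values)


@pytest.fixture(scope="module")
def indicator_maps(stack, stress_results):
    return {
        lb: stress_results[lb].project(stack, "wheat", "ZnO",
                                       measured_tissue="leaf")
        for lb in OXIDATIVE_LABELS
    }


class TestRiskLevels:

    def test_levels_span_and_percentages_conserve(self, indicator_maps):
        risk = oxidative_risk_levels(indicator_maps)
        valid = risk.levels[risk.mask]
        assert valid.min() >= 1 and valid.max() == 20
        assert set(valid) == set(range(1, 21))
        assert risk.area_percentages.sum() == pytest.approx(100.0, abs=1e-9)

    def test_levels_monotone_in_composite(self, indicator_maps):
        risk = oxidative_risk_levels(indicator_maps)
        comp = risk.composite[risk.mask]
        lev = risk.levels[risk.mask]
        order = np.argsort(comp, kind="stable")
        assert (np.diff(lev[order]) >= 0).all()

    def test_maximal_cell_gets_level_20(self, indicator_maps):
        risk = oxidative_risk_levels(indicator_maps)
        comp = np.where(risk.mask, risk.composite, -np.inf)
        i, j = np.unravel_index(np.nanargmax(comp), comp.shape)
        assert risk.levels[i, j] == 20

    def test_constant_maps_collapse_to_one_level(self, indicator_maps):
        template = next(iter(indicator_maps.values()))
        const = {
            lb: type(m)(np.where(m.mask, 0.4, np.nan), m.mask, lb)
            for lb, m in indicator_maps.items()
        }
        risk = oxidative_risk_levels(const)
        valid = risk.levels[risk.mask]
        assert len(set(valid)) == 1
        # normalisation maximum equals the constant composite
        assert np.nanmax(risk.composite) == pytest.approx(1.0)

    def test_zero_composite_warns_level_one(self, indicator_maps):
        zero = {
            lb: type(m)(np.where(m.mask, 0.0, np.nan), m.mask, lb)
            for lb, m in indicator_maps.items()
        }
        with pytest.warns(UserWarning, match="zero"):
            risk = oxidative_risk_levels(zero)
        assert (risk.levels[risk.mask] == 1).all()

    def test_mean_of_abs_alternative(self, indicator_maps):
        a = oxidative_risk_levels(indicator_maps, composite_mode="abs_of_mean")
        b = oxidative_risk_levels(indicator_maps, composite_mode="mean_of_abs")
        # mean of |x| dominates |mean x| pointwise (triangle inequality),
        # both normalised to max 1
        assert np.nanmax(b.composite) == pytest.approx(1.0)
        assert a.area_percentages.sum() == pytest.approx(100.0)


class TestScenarios:
    def test_zero_offset_identity(self, stack):
        out = apply_scenario(stack, ScenarioSpec("none"))
        for name in stack.layers:
            np.testing.assert_array_equal(out.layers[name], stack.layers[name])

    def test_scalar_offset_additive(self, stack):
        out = apply_scenario(stack, ScenarioSpec("SSP585", 6.0, 5.9))
        np.testing.assert_allclose(
            out.layer("daytime_temperature") - stack.layer("daytime_temperature"), 6.0
        )
        np.testing.assert_allclose(
            out.layer("night_temperature") - stack.layer("night_temperature"), 5.9
        )
        np.testing.assert_array_equal(out.layer("soil_pH"), stack.layer("soil_pH"))

    def test_warming_moves_response_in_planted_direction(self, stack, stress_results):
        """The length model was planted with a positive daytime-temperature
        effect, so a strong warming scenario raises the mean response."""
        res = stress_results["length"]
        base = res.project(stack, "wheat", "ZnO")
        # daytime warming only: the planted daytime effect is positive while
        # the night effect is negative, so shift just the beneficial layer
        warmed_stack = apply_scenario(stack, ScenarioSpec("hot-days", 8.0, 0.0))
        warmed = res.project(warmed_stack, "wheat", "ZnO")
        assert warmed.mean() > base.mean()

    def test_nonfinite_offsets_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("bad", float("nan"), 0.0)


class TestUncertainty:
    def test_summary_contract(self, stack, stress_results):
        res = stress_results["length"]
        grid = build_grid_features(stack, "wheat", "ZnO")
        unc = uncertainty_map(res.encoded, res.model.y,
                              ForestSpec(ntree=15, seed=0), grid,
                              runs=5, seed=0)
        assert unc.runs == 5
        valid = grid.mask
        assert (unc.sd[valid] >= 0).all()
        assert np.isnan(unc.mean[~valid]).all()

    def test_relative_uncertainty_shrinks_with_n(self, stack):
        rels = []
        for n in (100, 600):
            spec = EffectSpec(n=n, effects={"total_dose": 30.0},
                              noise_sd=5.0, seed=9, label_set=("length",))
            table = generate_experiment_table(spec)
            res = PlantResponseForest.from_dataframe(
                table, "length", ForestSpec(ntree=15, seed=0)
            ).fit()
            grid = build_grid_features(stack, "wheat", "ZnO")
            unc = uncertainty_map(res.encoded, res.model.y,
                                  ForestSpec(ntree=15, seed=0), grid,
                                  runs=8, seed=1)
            ok = ~unc.undefined & grid.mask
            rels.append(np.nanmedian(np.abs(unc.relative[ok])))
        assert rels[1] < rels[0]

    def test_too_few_runs_rejected(self, stack, stress_results):
        res = stress_results["length"]
        grid = build_grid_features(stack, "wheat", "ZnO")
        with pytest.raises(ValueError):
            uncertainty_map(res.encoded, res.model.y, ForestSpec(ntree=5),
                            grid, runs=1)
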