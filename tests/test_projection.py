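"""Scenario projection, ensembles, binary maps, stability, host comparison."""

import numpy as np
import pytest
from scipy import ndimage

from paleosdm.evaluation import ThresholdResult
from paleosdm.filtering import sample_background
from paleosdm.grids import EnvSample, GridSpec, Raster, extract_values
from paleosdm.maxent import count_parameters, fit_maxent, predict_maxent
from paleosdm.projection import (
    CODE_GAINED,
    CODE_LOST,
    CODE_NEVER,
    CODE_STABLE,
    NODATA_CODE,
    BinaryMap,
    ComparisonSettings,
    binarize,
    compare_with_without_host,
    ensemble_average,
    host_predictor_layer,
    overlap_change,
    project,
    stability_classify,
)
from paleosdm.synthetic import (
    ClimateSimConfig,
    TrueNiche,
    generate_scenarios,
    sample_occurrences,
    true_suitability,
)


@pytest.fixture(scope="module")
def world():
    cfg = ClimateSimConfig(grid=GridSpec(40, 40, -75.0, 5.0, 0.5), seed=19)
    scenarios = generate_scenarios(cfg)
    niche = TrueNiche(
        optima={"bio4": 1700.0, "bio16": 1800.0}, breadths={"bio4": 500.0, "bio16": 400.0}
    )
    cur = scenarios["current"]
    occ = sample_occurrences(true_suitability(niche, cur), 150, seed=1)
    pres = extract_values(cur, occ).sample
    bg = sample_background(cur, 1500, seed=2)
    model = fit_maxent(pres, bg)
    return scenarios, model, pres, bg


def random_binary(spec, seed, p=0.5, mask=None):
    rng = np.random.default_rng(seed)
    vals = (rng.uniform(size=(spec.n_rows, spec.n_cols)) < p).astype(np.int8)
    if mask is not None:
        vals[mask] = NODATA_CODE
    return BinaryMap(spec, vals)


class TestProject:
    def test_consistent_with_pointwise_prediction(self, world):
        scenarios, model, pres, _ = world
        cur = scenarios["current"]
        surface = project(model, cur)
        rows, cols = cur.valid_cells()
        env = EnvSample(
            point_ids=list(range(rows.size)),
            matrix=cur.matrix_at_cells(rows, cols),
            variable_names=cur.layer_names,
        )
        np.testing.assert_allclose(
            surface.values[rows, cols], predict_maxent(model, env), rtol=0, atol=0
        )

    def test_masked_cells_stay_masked(self, world):
        scenarios, model, _, _ = world
        cur = scenarios["current"]
        surface = project(model, cur)
        np.testing.assert_array_equal(surface.valid_mask, cur.valid_mask)

    def test_zero_model_gives_flat_half_surface(self, world):
        scenarios, model, pres, bg = world
        flat = fit_maxent(pres, bg, beta_multiplier=1e6)
        surface = project(flat, scenarios["current"])
        assert np.all(surface.values[surface.valid_mask] == 0.5)

    def test_spot_check_against_direct_formula(self, world):
        scenarios, model, _, _ = world
        cur = scenarios["current"]
        surface = project(model, cur)
        rows, cols = cur.valid_cells()
        rng = np.random.default_rng(0)
        pick = rng.choice(rows.size, size=20, replace=False)
        from scipy.special import expit

        for i in pick:
            r, c = rows[i], cols[i]
            feats = []
            x = {v: cur.get(v).values[r, c] for v in cur.layer_names}
            for f in model.features:
                if f.kind == "linear":
                    feats.append(x[f.variables[0]])
                else:
                    feats.append(x[f.variables[0]] ** 2)
            z = (np.array(feats) - model.feature_means) / model.feature_scales
            eta = float(z @ model.coefficients)
            assert surface.values[r, c] == pytest.approx(
                float(expit(eta - model.avg_gain)), abs=1e-12
            )

    def test_missing_layer_rejected(self, world):
        scenarios, model, _, _ = world
        cur = scenarios["current"]
        partial_stack = type(cur)(cur.layers[:2], "partial")
        with pytest.raises(KeyError):
            project(model, partial_stack)


class TestEnsemble:
    def test_identity_and_midpoint(self, small_spec):
        a = Raster(small_spec, np.zeros((4, 5)), "a")
        b = Raster(small_spec, np.ones((4, 5)), "b")
        np.testing.assert_array_equal(ensemble_average([a, a]).values, a.values)
        np.testing.assert_array_equal(
            ensemble_average([a, b]).values, np.full((4, 5), 0.5)
        )

    def test_elementwise_mean_oracle(self, small_spec):
        rng = np.random.default_rng(5)
        rasters = [
            Raster(small_spec, rng.uniform(size=(4, 5)), f"m{i}") for i in range(3)
        ]
        out = ensemble_average(rasters)
        expected = (rasters[0].values + rasters[1].values + rasters[2].values) / 3
        np.testing.assert_allclose(out.values, expected, atol=1e-15)

    def test_misaligned_rejected(self, small_spec):
        other = GridSpec(4, 5, 0.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            ensemble_average(
                [
                    Raster(small_spec, np.zeros((4, 5)), "a"),
                    Raster(other, np.zeros((4, 5)), "b"),
                ]
            )


class TestBinarize:
    def test_sentinel_thresholds(self, small_spec):
        rng = np.random.default_rng(1)
        vals = rng.uniform(size=(4, 5))
        vals[2, 2] = small_spec.nodata_value
        r = Raster(small_spec, vals, "s")
        all_suitable = binarize(r, -np.inf)
        assert all_suitable.n_suitable == 19
        none_suitable = binarize(r, np.nanmax(vals[vals != small_spec.nodata_value]) + 1)
        assert none_suitable.n_suitable == 0

    def test_direct_comparison_oracle_and_monotonicity(self, small_spec):
        rng = np.random.default_rng(2)
        vals = rng.uniform(size=(4, 5))
        r = Raster(small_spec, vals, "s")
        counts = []
        for thr in np.linspace(0, 1, 11):
            bm = binarize(r, thr)
            np.testing.assert_array_equal(bm.values == 1, vals >= thr)
            counts.append(bm.n_suitable)
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_accepts_threshold_result(self, small_spec):
        r = Raster(small_spec, np.full((4, 5), 0.6), "s")
        bm = binarize(r, ThresholdResult(0.5, 1.0, 1.0))
        assert bm.n_suitable == 20


class TestStability:
    def test_identical_maps_only_stable_or_never(self, small_spec):
        bm = random_binary(small_spec, 3)
        stab = stability_classify(bm, bm)
        assert set(np.unique(stab.values)) <= {CODE_NEVER, CODE_STABLE}

    def test_total_loss(self, small_spec):
        past = BinaryMap(small_spec, np.ones((4, 5), dtype=np.int8))
        present = BinaryMap(small_spec, np.zeros((4, 5), dtype=np.int8))
        stab = stability_classify(past, present)
        assert stab.counts() == {"never": 0, "stable": 0, "lost": 20, "gained": 0}

    @pytest.mark.parametrize("seed", range(4))
    def test_counts_equal_brute_force_intersections(self, small_spec, seed):
        mask = np.zeros((4, 5), dtype=bool)
        mask[0, 0] = True
        past = random_binary(small_spec, seed, mask=mask)
        present = random_binary(small_spec, seed + 100, mask=mask)
        stab = stability_classify(past, present)
        p = past.values == 1
        q = present.values == 1
        valid = ~mask
        expected = {
            "never": int(np.sum(valid & ~p & ~q)),
            "stable": int(np.sum(valid & p & q)),
            "lost": int(np.sum(valid & p & ~q)),
            "gained": int(np.sum(valid & ~p & q)),
        }
        assert stab.counts() == expected
        # the four categories partition the valid cells
        assert sum(expected.values()) == int(valid.sum())

    def test_misaligned_rejected(self, small_spec):
        other = GridSpec(4, 5, 0.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            stability_classify(
                random_binary(small_spec, 1),
                BinaryMap(other, np.zeros((4, 5), dtype=np.int8)),
            )


class TestOverlap:
    def test_identical_scenarios_no_change(self, small_spec):
        para = random_binary(small_spec, 7)
        host = random_binary(small_spec, 8)
        res = overlap_change(para, host, para, host)
        assert res.change_percent == 0.0

    def test_nested_ranges_full_overlap(self, small_spec):
        host = BinaryMap(small_spec, np.ones((4, 5), dtype=np.int8))
        para = random_binary(small_spec, 9)
        res = overlap_change(para, host, para, host)
        assert res.overlap_past == 1.0 and res.overlap_present == 1.0
        assert res.change_percent == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_brute_force_set_arithmetic(self, small_spec, seed):
        maps = [random_binary(small_spec, seed * 10 + i) for i in range(4)]
        res = overlap_change(*maps)

        def brute(parasite, host):
            num = den = 0
            for r in range(4):
                for c in range(5):
                    if parasite.values[r, c] == 1:
                        den += 1
                        if host.values[r, c] == 1:
                            num += 1
            return num / den

        expected = abs(brute(maps[2], maps[3]) - brute(maps[0], maps[1])) * 100
        assert res.change_percent == pytest.approx(expected, abs=1e-12)

    def test_empty_parasite_range_undefined(self, small_spec):
        empty = BinaryMap(small_spec, np.zeros((4, 5), dtype=np.int8))
        host = random_binary(small_spec, 2)
        res = overlap_change(empty, host, random_binary(small_spec, 3), host)
        assert not res.defined


class TestHostLayer:
    def test_indicator_oracle_and_nodata(self, small_spec):
        vals = np.array(
            [[1, 0, 1, 0, 1]] * 2 + [[0, 1, 0, 1, 0]] * 2, dtype=np.int8
        )
        vals[1, 1] = NODATA_CODE
        bm = BinaryMap(small_spec, vals)
        layer = host_predictor_layer(bm)
        for r in range(4):
            for c in range(5):
                if vals[r, c] == NODATA_CODE:
                    assert layer.values[r, c] == layer.spec.nodata_value
                else:
                    assert layer.values[r, c] == float(vals[r, c])

    def test_constant_layer_warns(self, small_spec):
        bm = BinaryMap(small_spec, np.ones((4, 5), dtype=np.int8))
        with pytest.warns(UserWarning, match="zero variance"):
            host_predictor_layer(bm)

    def test_roundtrip_through_binarize(self, small_spec):
        bm = random_binary(small_spec, 13)
        layer = host_predictor_layer(bm)
        back = binarize(layer, 0.5)
        np.testing.assert_array_equal(back.values, bm.values)


class TestHostComparison:
    def test_constant_host_layer_changes_nothing(self, world):
        """An uninformative (constant) host predictor is pinned at zero, so
        both models have the same k and AICc and the difference map is empty."""
        scenarios, model, pres, bg = world
        cur = scenarios["current"]
        niche = TrueNiche(optima={"bio16": 1800.0}, breadths={"bio16": 400.0})
        occ = sample_occurrences(true_suitability(niche, cur), 60, seed=3)
        ones = BinaryMap(
            cur.spec,
            np.where(cur.valid_mask, 1, NODATA_CODE).astype(np.int8),
        )
        with pytest.warns(UserWarning):
            layer = host_predictor_layer(ones)
        res = compare_with_without_host(
            occ, cur, layer, ComparisonSettings(n_background=1000, seed=4)
        )
        k_climate = count_parameters(res.model_climate)
        k_host = count_parameters(res.model_with_host)
        assert k_climate == k_host
        assert res.comparison.delta_aicc == [0.0, 0.0]
        assert res.lost_by_host_map.n_suitable == 0

    def test_informative_host_layer_reported(self, world):
        scenarios, *_ = world
        cur = scenarios["current"]
        rng = np.random.default_rng(21)
        blob = ndimage.uniform_filter(
            rng.standard_normal(cur.valid_mask.shape), size=11, mode="nearest"
        )
        host_vals = np.where(
            cur.valid_mask, (blob > np.quantile(blob, 0.5)).astype(np.int8), NODATA_CODE
        ).astype(np.int8)
        host_map = BinaryMap(cur.spec, host_vals)
        layer = host_predictor_layer(host_map)
        clim = true_suitability(
            TrueNiche(optima={"bio16": 1800.0}, breadths={"bio16": 400.0}), cur
        )
        product = Raster(
            cur.spec,
            np.where(
                cur.valid_mask,
                clim.values * (host_vals == 1),
                cur.spec.nodata_value,
            ),
            "s",
        )
        occ = sample_occurrences(product, 120, seed=5)
        res = compare_with_without_host(
            occ, cur, layer, ComparisonSettings(n_background=1500, seed=6)
        )
        # parasite truly confined to the host blob: the augmented model wins
        assert res.comparison.best_label == "climate_plus_host"
        host_coef = [
            c for f, c in zip(res.model_with_host.features, res.model_with_host.coefficients)
            if "host" in f.variables
        ]
        assert host_coef and host_coef[0] > 0
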