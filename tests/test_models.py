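"""Ensemble fitting, quantile surfaces and the composition stack."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from wildmeat.grids import Grid, GridStack, extract_features
from wildmeat.models import (
    EnsembleSpec,
    assemble_tsop_stack,
    build_tsop_training,
    fit_hhr_ensemble,
    fit_predict_tsop,
    predict_hp,
)
from wildmeat.records import compute_hhr, compute_tsop, efforts_for, filter_studies

SMALL_SPEC = EnsembleSpec(n_members=5, n_trees=50, seed=77)


@pytest.fixture(scope="module")
def training(landscape, communities, hunting_data):
    """Feature table and per-locality harvest rates on the session fixture."""
    records, efforts = hunting_data
    _, hhr_records = filter_studies(records, efforts)
    hhr = compute_hhr(hhr_records, efforts_for(hhr_records, efforts))
    years = efforts.set_index("locality_id")["year"]
    feats = extract_features(landscape.stack, communities,
                            years=years.reindex(communities["locality_id"]))
    feats = feats.merge(efforts[["locality_id", "span_days"]], on="locality_id")
    train = feats[feats["locality_id"].isin(hhr.index)].drop_duplicates("locality_id")
    y = hhr.loc[train["locality_id"]].to_numpy()
    return train, y


@pytest.fixture(scope="module")
def fitted(training):
    train, y = training
    return fit_hhr_ensemble(train, y, SMALL_SPEC)


class TestEnsembleSpec:
    def test_invalid_subsample_rejected(self):
        with pytest.raises(ValueError):
            EnsembleSpec(subsample_fraction=0.0)

    def test_unsorted_quantiles_rejected(self):
        with pytest.raises(ValueError):
            EnsembleSpec(quantiles=(0.5, 0.25))


class TestHHREnsemble:
    def test_constant_response_predicts_constant(self, training, landscape):
        train, y = training
        with pytest.warns(UserWarning, match="constant"):
            ens = fit_hhr_ensemble(train, np.full_like(y, 0.05), SMALL_SPEC)
        surf = predict_hp(ens, landscape.stack)
        ok = ~surf.q50.mask
        np.testing.assert_allclose(surf.q10.values[ok], 0.05, atol=1e-12)
        np.testing.assert_allclose(surf.q90.values[ok], 0.05, atol=1e-12)

    def test_seeded_refit_reproducible(self, training, landscape):
        train, y = training
        a = predict_hp(fit_hhr_ensemble(train, y, SMALL_SPEC), landscape.stack)
        b = predict_hp(fit_hhr_ensemble(train, y, SMALL_SPEC), landscape.stack)
        np.testing.assert_array_equal(a.q50.values, b.q50.values)

    def test_quantiles_monotone_cellwise(self, fitted, landscape):
        surf = predict_hp(fitted, landscape.stack)
        ok = ~surf.q50.mask
        assert (surf.q10.values[ok] <= surf.q25.values[ok] + 1e-12).all()
        assert (surf.q25.values[ok] <= surf.q50.values[ok] + 1e-12).all()
        assert (surf.q50.values[ok] <= surf.q75.values[ok] + 1e-12).all()
        assert (surf.q75.values[ok] <= surf.q90.values[ok] + 1e-12).all()

    def test_mean_is_average_of_five_quantile_grids(self, fitted, landscape):
        surf = predict_hp(fitted, landscape.stack)
        stack = np.stack([surf.q10.values, surf.q25.values, surf.q50.values,
                          surf.q75.values, surf.q90.values])
        np.testing.assert_allclose(surf.mean.values, stack.mean(axis=0), atol=1e-12)

    def test_single_member_collapses_quantiles(self, training, landscape):
        train, y = training
        ens = fit_hhr_ensemble(train, y, EnsembleSpec(n_members=1, n_trees=30, seed=1))
        surf = predict_hp(ens, landscape.stack)
        np.testing.assert_array_equal(surf.q10.values, surf.q90.values)

    def test_predictions_nonnegative(self, fitted, landscape):
        surf = predict_hp(fitted, landscape.stack)
        for g in surf.grids().values():
            assert (g.values >= 0).all()

    def test_removing_driver_degrades_recovery(self, training, landscape):
        """Dropping the covariate that truly drives the rate lowers Spearman."""
        train, y = training
        ok = landscape.boundary_mask
        full = fit_hhr_ensemble(train, y, SMALL_SPEC)
        rho_full = spearmanr(
            predict_hp(full, landscape.stack).q50.values[ok], landscape.true_hp[ok]
        ).statistic
        crippled = fit_hhr_ensemble(train.drop(columns=["evi"]), y, SMALL_SPEC)
        rho_crippled = spearmanr(
            predict_hp(crippled, landscape.stack).q50.values[ok], landscape.true_hp[ok]
        ).statistic
        assert rho_crippled < rho_full

    def test_importances_cover_all_features(self, fitted):
        assert set(fitted.importances.index) == set(fitted.feature_names)


class TestTSOPTraining:
    LOCS = pd.DataFrame({"locality_id": ["A", "B", "C"], "row": [0, 0, 1],
                         "col": [0, 1, 1]})

    def _tsop(self, data):
        return pd.DataFrame(data).set_index("locality_id")

    def test_in_range_absence_becomes_zero_row(self):
        tsop = self._tsop([{"locality_id": "A", "t1": 0.6, "t2": 0.4},
                           {"locality_id": "B", "t1": 1.0, "t2": 0.0}])
        mask = np.ones((2, 2), dtype=bool)
        rows = build_tsop_training(tsop, self.LOCS, "t2", mask)
        by_loc = rows.set_index("locality_id")["tsop"]
        assert by_loc.loc["A"] == pytest.approx(0.4)
        assert by_loc.loc["B"] == 0.0

    def test_out_of_range_absence_contributes_nothing(self):
        tsop = self._tsop([{"locality_id": "A", "t1": 0.6, "t2": 0.4},
                           {"locality_id": "B", "t1": 1.0, "t2": 0.0}])
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True  # only A's cell in range
        rows = build_tsop_training(tsop, self.LOCS, "t2", mask)
        assert set(rows["locality_id"]) == {"A"}

    def test_nested_taxon_localities_excluded(self):
        registry = pd.DataFrame({"taxon_id": ["Mazama americana", "Mazama spp."],
                                 "parent_id": ["Mazama spp.", None]})
        tsop = self._tsop([
            {"locality_id": "A", "Mazama americana": 0.5, "Mazama spp.": 0.5},
            {"locality_id": "B", "Mazama americana": 0.7, "Mazama spp.": 0.0},
        ])
        rows = build_tsop_training(tsop, self.LOCS, "Mazama americana",
                                   np.ones((2, 2), bool), registry)
        assert set(rows["locality_id"]) == {"B"}


class TestTSOPFitPredict:
    def _mini_stack(self, n=8):
        rng = np.random.default_rng(0)
        x = Grid(np.tile(np.linspace(-1, 1, n), (n, 1)), tag="x1")
        noise = Grid(rng.normal(size=(n, n)), tag="x2")
        return GridStack(static={"x1": x, "x2": noise})

    def _features(self, stack, locs):
        return extract_features(stack, locs)

    def test_all_zero_training_gives_zero_surface(self):
        stack = self._mini_stack()
        locs = pd.DataFrame({"locality_id": [f"L{i}" for i in range(12)],
                             "row": np.arange(12) % 8, "col": np.arange(12) % 8})
        feats = self._features(stack, locs)
        train = pd.DataFrame({"locality_id": locs["locality_id"], "tsop": 0.0})
        surface, modelled = fit_predict_tsop(train, feats, stack, SMALL_SPEC)
        assert modelled
        assert (surface.values == 0).all()

    def test_sparse_taxon_falls_back_to_constant(self):
        stack = self._mini_stack()
        locs = pd.DataFrame({"locality_id": ["L0", "L1"], "row": [0, 1], "col": [0, 1]})
        feats = self._features(stack, locs)
        train = pd.DataFrame({"locality_id": ["L0", "L1"], "tsop": [0.2, 0.4]})
        surface, modelled = fit_predict_tsop(train, feats, stack, SMALL_SPEC)
        assert not modelled
        assert np.allclose(surface.values[~surface.mask], 0.3)

    def test_predictions_clipped_to_unit_interval(self, landscape, communities,
                                                  hunting_data, taxa_bundle):
        records, efforts = hunting_data
        tsop = compute_tsop(records)
        feats = extract_features(landscape.stack, communities,
                                 years={l: [2010] for l in communities["locality_id"]})
        profiles, ranges, _ = taxa_bundle
        t = profiles[1].taxon_id
        train = build_tsop_training(tsop, communities, t, ranges[t])
        surface, _ = fit_predict_tsop(train, feats, landscape.stack, SMALL_SPEC)
        assert (surface.values >= 0).all() and (surface.values <= 1).all()

    def test_spatially_separated_taxa_recovered(self):
        """Each taxon's raw surface is higher inside its own preference region."""
        stack = self._mini_stack(10)
        rng = np.random.default_rng(4)
        rows = rng.integers(0, 10, 40)
        cols = rng.integers(0, 10, 40)
        locs = pd.DataFrame({"locality_id": [f"L{i}" for i in range(40)],
                             "row": rows, "col": cols})
        feats = self._features(stack, locs)
        x1 = stack.static["x1"].values[rows, cols]
        west = pd.DataFrame({"locality_id": locs["locality_id"],
                             "tsop": np.where(x1 < 0, 0.8, 0.1)})
        east = pd.DataFrame({"locality_id": locs["locality_id"],
                             "tsop": np.where(x1 < 0, 0.1, 0.8)})
        s_west, _ = fit_predict_tsop(west, feats, stack, SMALL_SPEC)
        s_east, _ = fit_predict_tsop(east, feats, stack, SMALL_SPEC)
        half = stack.static["x1"].values < 0
        assert s_west.values[half].mean() > s_west.values[~half].mean()
        assert s_east.values[~half].mean() > s_east.values[half].mean()


class TestAssembleStack:
    def test_renormalization(self):
        a = Grid(np.full((2, 2), 0.3), tag="a")
        b = Grid(np.full((2, 2), 0.1), tag="b")
        out = assemble_tsop_stack({"a": a, "b": b},
                                  {"a": np.ones((2, 2), bool), "b": np.ones((2, 2), bool)})
        np.testing.assert_allclose(out.proportions["a"].values, 0.75)
        np.testing.assert_allclose(out.proportions["b"].values, 0.25)

    def test_single_in_range_taxon_gets_one(self):
        a = Grid(np.full((2, 2), 0.3), tag="a")
        b = Grid(np.full((2, 2), 0.4), tag="b")
        only_a = {"a": np.ones((2, 2), bool), "b": np.zeros((2, 2), bool)}
        out = assemble_tsop_stack({"a": a, "b": b}, only_a)
        np.testing.assert_allclose(out.proportions["a"].values[out.valid], 1.0)
        assert (out.proportions["b"].values == 0).all()

    def test_zero_sum_cells_masked(self):
        a = Grid(np.zeros((2, 2)), tag="a")
        out = assemble_tsop_stack({"a": a}, {"a": np.ones((2, 2), bool)})
        assert not out.valid.any()

    def test_cellwise_sums_to_one_on_fixture(self, landscape, taxa_bundle, rng):
        profiles, ranges, _ = taxa_bundle
        raw = {
            p.taxon_id: Grid(
                np.abs(rng.normal(0.2, 0.1, landscape.shape)), tag=p.taxon_id
            )
            for p in profiles
        }
        out = assemble_tsop_stack(raw, ranges)
        sums = out.sum_surface()
        np.testing.assert_allclose(sums[out.valid], 1.0, atol=1e-9)
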