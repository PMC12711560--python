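"""Harvest-rate, composition, ratio and Monte Carlo metric behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wildmeat.errors import EffortError, ReclassificationError, UndefinedTSOPError
from wildmeat.records import (
    MetricEstimate,
    UNDETERMINED,
    apply_reclassification,
    compute_hhr,
    compute_tsop,
    filter_studies,
    hunter_consumer_ratio,
    monte_carlo_metric,
    summarize_traits,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["locality_id", "year", "taxon_id", "n_individuals"])


class TestReclassification:
    def test_identity_mapping_conserves_counts(self):
        raw = _records([("L1", 2000, "Mazama americana", 3),
                        ("L1", 2000, "Mazama nemorivaga", 2)])
        out = apply_reclassification(
            raw, {"Mazama americana": "Mazama americana",
                  "Mazama nemorivaga": "Mazama nemorivaga"}
        )
        assert out["n_individuals"].sum() == 5
        assert set(out["taxon_id"]) == {"Mazama americana", "Mazama nemorivaga"}

    def test_vernacular_merge(self):
        raw = _records([("L1", 2000, "red brocket", 3),
                        ("L1", 2000, "Mazama americana", 4)])
        out = apply_reclassification(
            raw, {"red brocket": "Mazama americana",
                  "Mazama americana": "Mazama americana"}
        )
        assert len(out) == 1
        assert out["n_individuals"].iloc[0] == 7

    def test_unmapped_label_raises_with_names(self):
        raw = _records([("L1", 2000, "mystery beast", 1)])
        with pytest.raises(ReclassificationError, match="mystery beast"):
            apply_reclassification(raw, {})

    def test_many_species_collapse_to_analysis_taxa(self):
        """438 raw species labels mapped into 173 taxa + undetermined -> 174 labels."""
        rng = np.random.default_rng(0)
        raw_labels = [f"species_{i:03d}" for i in range(438)]
        mapping = {lab: f"taxon_{i % 173:03d}" for i, lab in enumerate(raw_labels)}
        mapping[raw_labels[-1]] = UNDETERMINED
        raw = _records([("L1", 2000, lab, int(rng.integers(1, 5))) for lab in raw_labels])
        out = apply_reclassification(raw, mapping)
        assert out["taxon_id"].nunique() == 174
        assert out["n_individuals"].sum() == raw["n_individuals"].sum()


class TestFilters:
    EFF = pd.DataFrame({"locality_id": ["A", "B"], "n_hunters": [5, 5],
                        "span_days": [100, 100], "year": [2000, 2000]})

    def test_sparse_locality_dropped_everywhere(self):
        rec = _records([("A", 2000, f"t{i}", 1) for i in range(3)]
                       + [("B", 2000, f"t{i}", 1) for i in range(5)])
        tsop, hhr = filter_studies(rec, self.EFF)
        assert set(tsop["locality_id"]) == {"B"}
        assert set(hhr["locality_id"]) == {"B"}

    def test_no_effort_kept_for_composition_only(self):
        rec = _records([("C", 2000, f"t{i}", 1) for i in range(5)])
        tsop, hhr = filter_studies(rec, self.EFF)
        assert set(tsop["locality_id"]) == {"C"}
        assert len(hhr) == 0

    def test_rich_localities_with_effort_identical_coverage(self):
        rec = _records([(loc, 2000, f"t{i}", 1) for loc in ("A", "B") for i in range(4)])
        tsop, hhr = filter_studies(rec, self.EFF)
        assert set(tsop["locality_id"]) == set(hhr["locality_id"]) == {"A", "B"}

    def test_undetermined_does_not_count_toward_threshold(self):
        rec = _records([("A", 2000, "t1", 1), ("A", 2000, "t2", 1),
                        ("A", 2000, "t3", 1), ("A", 2000, UNDETERMINED, 10)])
        tsop, _ = filter_studies(rec, self.EFF)
        assert len(tsop) == 0


class TestHHR:
    def test_arithmetic(self):
        rec = _records([("A", 2000, "t1", 100)])
        eff = pd.DataFrame({"locality_id": ["A"], "n_hunters": [5],
                            "span_days": [100], "year": [2000]})
        assert compute_hhr(rec, eff).loc["A"] == pytest.approx(0.2)

    def test_zero_harvest_gives_zero(self):
        rec = _records([])
        eff = pd.DataFrame({"locality_id": ["A"], "n_hunters": [2],
                            "span_days": [10], "year": [2000]})
        assert compute_hhr(rec, eff).loc["A"] == 0.0

    def test_zero_effort_raises(self):
        rec = _records([("A", 2000, "t1", 1)])
        eff = pd.DataFrame({"locality_id": ["A"], "n_hunters": [0],
                            "span_days": [10], "year": [2000]})
        with pytest.raises(EffortError):
            compute_hhr(rec, eff)

    @given(total_hunters=st.integers(2, 40), split=st.integers(1, 39),
           days=st.integers(1, 400), kills=st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_splitting_effort_rows(self, total_hunters, split, days, kills):
        split = min(split, total_hunters - 1)
        rec = _records([("A", 2000, "t1", kills)])
        one = pd.DataFrame({"locality_id": ["A"], "n_hunters": [total_hunters],
                            "span_days": [days], "year": [2000]})
        two = pd.DataFrame({"locality_id": ["A", "A"],
                            "n_hunters": [split, total_hunters - split],
                            "span_days": [days, days], "year": [2000, 2000]})
        assert compute_hhr(rec, one).loc["A"] == pytest.approx(compute_hhr(rec, two).loc["A"])

    def test_poisson_simulation_recovers_rate(self):
        """Pooled HHR across 100 localities within 3 s.e. of the true 0.07."""
        rng = np.random.default_rng(7)
        true_rate, hunters, days = 0.07, 8, 150
        rows, eff_rows = [], []
        for i in range(100):
            kills = rng.poisson(true_rate * hunters * days)
            rows.append((f"L{i}", 2000, "t1", kills))
            eff_rows.append((f"L{i}", hunters, days, 2000))
        rec = _records(rows)
        eff = pd.DataFrame(eff_rows, columns=["locality_id", "n_hunters",
                                              "span_days", "year"])
        hhr = compute_hhr(rec, eff)
        total_effort = 100 * hunters * days
        pooled = rec["n_individuals"].sum() / total_effort
        se = np.sqrt(true_rate / total_effort)
        assert abs(pooled - true_rate) < 3 * se
        assert len(hhr) == 100


class TestTSOP:
    def test_proportions(self):
        rec = _records([("A", 2000, "a", 30), ("A", 2000, "b", 10)])
        tsop = compute_tsop(rec)
        assert tsop.loc["A", "a"] == pytest.approx(0.75)
        assert tsop.loc["A", "b"] == pytest.approx(0.25)

    def test_single_taxon_locality(self):
        tsop = compute_tsop(_records([("A", 2000, "a", 7)]))
        assert tsop.loc["A", "a"] == 1.0

    def test_rows_sum_to_one(self, hunting_data):
        records, _ = hunting_data
        tsop = compute_tsop(records)
        np.testing.assert_allclose(tsop.sum(axis=1), 1.0, atol=1e-12)
        assert ((tsop >= 0) & (tsop <= 1)).all().all()

    def test_zero_total_raises(self):
        with pytest.raises(UndefinedTSOPError):
            compute_tsop(_records([("A", 2000, "a", 0)]))

    def test_multinomial_concentration(self):
        rng = np.random.default_rng(3)
        counts = rng.multinomial(10_000, [0.5, 0.3, 0.2])
        rec = _records([("A", 2000, t, int(n)) for t, n in zip("abc", counts)])
        tsop = compute_tsop(rec)
        for taxon, p in zip("abc", (0.5, 0.3, 0.2)):
            assert tsop.loc["A", taxon] == pytest.approx(p, abs=0.02)


class TestHunterRatio:
    def test_median_of_ratios(self):
        df = pd.DataFrame({"n_hunters": [1, 2, 3], "n_consumers": [10, 10, 10]})
        assert hunter_consumer_ratio(df).q50 == pytest.approx(0.2)

    def test_default_path_uses_published_constants(self):
        est = hunter_consumer_ratio(None)
        assert est.q50 == 0.178
        assert (est.q10, est.q25, est.q75, est.q90) == (0.168, 0.173, 0.183, 0.187)

    def test_binomial_fixture_recovers_median(self):
        rng = np.random.default_rng(5)
        consumers = rng.integers(50, 200, size=72)
        hunters = rng.binomial(consumers, 0.178)
        df = pd.DataFrame({"n_hunters": hunters, "n_consumers": consumers})
        assert hunter_consumer_ratio(df).q50 == pytest.approx(0.178, abs=0.02)

    def test_zero_consumers_excluded_with_warning(self):
        df = pd.DataFrame({"n_hunters": [1, 5], "n_consumers": [10, 0]})
        with pytest.warns(UserWarning):
            est = hunter_consumer_ratio(df)
        assert est.q50 == pytest.approx(0.1)


class TestMonteCarlo:
    def test_zero_se_is_point_mass(self):
        est = monte_carlo_metric(5.0, 0.0, seed=0)
        assert est.sd == 0.0
        assert est.q10 == est.q90 == 5.0

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_metric(5.0, -1.0)

    def test_mean_recovery_large_sample(self):
        est = monte_carlo_metric(10.0, 1.0, n_draws=100_000, seed=1)
        assert est.mean == pytest.approx(10.0, abs=0.02)

    def test_interdecile_width_matches_normal(self):
        est = monte_carlo_metric(10.0, 1.0, n_draws=100_000, seed=2)
        expected = 2 * 1.2815515655446004 * 1.0
        assert est.q90 - est.q10 == pytest.approx(expected, rel=0.05)

    def test_positive_rejection_leaves_no_negative_draws(self):
        est = monte_carlo_metric(0.5, 1.0, n_draws=20_000, seed=3, positive=True)
        assert est.q10 > 0.0
        # rejection, not truncation: no atom sitting exactly at zero
        assert est.q10 != 0.0 and est.mean > 0.5

    def test_seeded_reproducibility(self):
        a = monte_carlo_metric(3.0, 0.7, seed=11)
        b = monte_carlo_metric(3.0, 0.7, seed=11)
        assert a == b

    def test_quantile_order_enforced(self):
        with pytest.raises(ValueError):
            MetricEstimate(0, 1, 0.5, 0.4, 0.6, 0.7, 0.8)


class TestTraitSummaries:
    def test_single_observation_is_point(self):
        obs = pd.DataFrame({"taxon_id": ["a"], "value": [4.2]})
        out = summarize_traits(obs, seed=0)
        assert out["a"].mean == pytest.approx(4.2)
        assert out["a"].sd == 0.0

    def test_se_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        small = pd.DataFrame({"taxon_id": "a", "value": rng.normal(10, 2, 5)})
        large = pd.DataFrame({"taxon_id": "a", "value": rng.normal(10, 2, 500)})
        assert summarize_traits(large, seed=1)["a"].sd < summarize_traits(small, seed=1)["a"].sd
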