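"""End-to-end pipeline runner.

Orders the stages: simulate/ingest -> filter -> metrics -> extract -> fit
HHR ensemble -> predict HP -> TSOP stack -> offtake -> edible -> per-capita
-> nutrition -> report. Every stage draws its randomness from a substream
derived from the single root seed, so two runs with the same config produce
byte-identical summary tables and manifests. Uncertainty is propagated
quantile-by-quantile: the q10 harvest-rate surface is combined with the q10
hunter ratio and q10 body masses, and so on, never mixing quantile levels.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import synthetic
from .config import PipelineConfig, STAGES
from .errors import StageError
from .grids import derive_apps, derive_rhps, extract_features, gap_fill
from .gridio import write_grid
from .models import (
    EnsembleSpec,
    QuantileSurface,
    assemble_tsop_stack,
    build_tsop_training,
    fit_hhr_ensemble,
    fit_predict_tsop,
    predict_hp,
)
from .nutrition import (
    adequacy_percent,
    load_default_composition,
    load_default_dri,
    load_default_shares,
    mean_nutrient_content,
    requirement_surfaces,
)
from .offtake import (
    beef_counterfactual,
    biomass_surfaces,
    density_cap_per_cell,
    edible_production,
    individuals_offtake,
    per_capita_availability,
    taxon_individual_hp,
)
from .records import (
    compute_hhr,
    compute_tsop,
    efforts_for,
    filter_studies,
    hunter_consumer_ratio,
)

log = logging.getLogger("wildmeat")

QUANTILE_KEYS = ("q10", "q25", "q50", "q75", "q90")


def _stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage substream seed below 2**31."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    """Artifacts of one run, kept in memory for programmatic use."""

    outdir: Path
    summary: pd.DataFrame
    taxon_summary: pd.DataFrame
    manifest: dict
    hp_surface: QuantileSurface | None = None
    extras: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute the full pipeline for one config; write artifacts to ``outdir``.

    Any stage failure aborts with :class:`StageError` naming the stage. The
    run manifest records the config, stage status, derived stage seeds and
    SHA-256 digests of every written table.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.as_dict(), "stages": {}, "digests": {}}
    state: dict = {}

    stage_fns = {
        "simulate": _stage_simulate,
        "filter": _stage_filter,
        "metrics": _stage_metrics,
        "extract": _stage_extract,
        "fit": _stage_fit,
        "predict": _stage_predict,
        "tsop": _stage_tsop,
        "offtake": _stage_offtake,
        "edible": _stage_edible,
        "per_capita": _stage_per_capita,
        "nutrition": _stage_nutrition,
        "report": _stage_report,
    }
    for stage in STAGES:
        if stage == "nutrition" and not config.run_nutrition:
            manifest["stages"][stage] = "skipped"
            log.info("stage %s: skipped", stage)
            continue
        seed = _stage_seed(config.seed, stage)
        try:
            stage_fns[stage](config, state, outdir, seed, manifest)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = "ok"
        log.info("stage %s: ok", stage)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        outdir=outdir,
        summary=state["summary"],
        taxon_summary=state["taxon_summary"],
        manifest=manifest,
        hp_surface=state.get("hp_surface"),
        extras=state,
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, state, outdir, seed, manifest):
    land_cfg = synthetic.LandscapeConfig(
        n_rows=config.n_rows, n_cols=config.n_cols, n_covariates=config.n_covariates,
        urban_fraction=config.urban_fraction, deforestation_max=config.deforestation_max,
        seed=seed,
    )
    landscape = synthetic.generate_landscape(land_cfg)
    taxa, ranges, mass_obs = synthetic.generate_taxa(
        config.n_taxa, landscape.shape, landscape.boundary_mask, seed=seed + 1
    )
    communities = synthetic.generate_communities(
        landscape, config.n_localities, config.true_hunter_ratio, seed=seed + 2
    )
    truth = synthetic.build_ground_truth(
        landscape, taxa, ranges, config.true_hunter_ratio, seed=seed + 3
    )
    if config.records_path:
        records = pd.read_csv(config.records_path)
        efforts = pd.read_csv(config.effort_path)
    else:
        records, efforts = synthetic.generate_hunting_records(
            communities, truth, effort_days=config.effort_days, seed=seed + 4
        )
    for name, df in (("records.csv", records), ("effort.csv", efforts),
                     ("traits_mass.csv", mass_obs),
                     ("localities.csv", communities)):
        path = outdir / name
        df.to_csv(path, index=False)
        manifest["digests"][name] = _sha256(path)
    state.update(landscape=landscape, taxa=taxa, ranges=ranges, truth=truth,
                 communities=communities, records=records, efforts=efforts)
    log.info("simulate: %d records at %d localities", len(records), len(communities))


def _stage_filter(config, state, outdir, seed, manifest):
    tsop_records, hhr_records = filter_studies(
        state["records"], state["efforts"], min_taxa=config.min_taxa_per_locality
    )
    state["tsop_records"] = tsop_records
    state["hhr_records"] = hhr_records
    log.info(
        "filter: %d localities for composition, %d for harvest rate",
        tsop_records["locality_id"].nunique(), hhr_records["locality_id"].nunique(),
    )


def _stage_metrics(config, state, outdir, seed, manifest):
    hhr_efforts = efforts_for(state["hhr_records"], state["efforts"])
    state["hhr"] = compute_hhr(state["hhr_records"], hhr_efforts)
    state["tsop"] = compute_tsop(state["tsop_records"])
    state["ratio"] = hunter_consumer_ratio(state["communities"])


def _stage_extract(config, state, outdir, seed, manifest):
    efforts = state["efforts"].set_index("locality_id")
    communities = state["communities"]
    years = efforts["year"].reindex(communities["locality_id"]).fillna(2020).astype(int)
    years.index = communities["locality_id"]
    stack = state["landscape"].stack
    # Gap-fill every layer before use so feature extraction and prediction
    # see a complete lattice inside the boundary.
    for tag, grid in list(stack.static.items()):
        stack.static[tag] = gap_fill(grid)
    for tag in stack.temporal:
        for ep, grid in list(stack.temporal[tag].items()):
            stack.temporal[tag][ep] = gap_fill(grid)
    features = extract_features(stack, communities, years=years)
    features = features.merge(
        efforts.reset_index()[["locality_id", "span_days"]], on="locality_id", how="left"
    )
    state["features"] = features


def _stage_fit(config, state, outdir, seed, manifest):
    spec = EnsembleSpec(
        n_members=config.n_members, subsample_fraction=config.subsample_fraction,
        n_trees=config.n_trees, seed=seed,
    )
    hhr = state["hhr"]
    features = state["features"]
    train = features[features["locality_id"].isin(hhr.index)].drop_duplicates("locality_id")
    y = hhr.loc[train["locality_id"]].to_numpy()
    state["ensemble"] = fit_hhr_ensemble(train, y, spec)
    state["tsop_spec"] = EnsembleSpec(
        n_members=1, subsample_fraction=1.0, n_trees=config.n_trees, seed=seed + 1
    )
    path = outdir / "importance.csv"
    state["ensemble"].importances.rename("importance").to_csv(path)
    manifest["digests"]["importance.csv"] = _sha256(path)


def _stage_predict(config, state, outdir, seed, manifest):
    surface = predict_hp(state["ensemble"], state["landscape"].stack)
    state["hp_surface"] = surface
    if config.write_surfaces:
        for name, grid in surface.grids().items():
            write_grid(grid, outdir / f"hp_{name}.tif")


def _stage_tsop(config, state, outdir, seed, manifest):
    features = state["features"].drop_duplicates("locality_id")
    raw = {}
    modelled = {}
    for t in state["taxa"]:
        training = build_tsop_training(
            state["tsop"], state["communities"], t.taxon_id, state["ranges"][t.taxon_id]
        )
        surface, ok = fit_predict_tsop(
            training, features, state["landscape"].stack, state["tsop_spec"]
        )
        raw[t.taxon_id] = surface
        modelled[t.taxon_id] = ok
    state["tsop_stack"] = assemble_tsop_stack(raw, state["ranges"])
    state["tsop_modelled"] = modelled


def _stage_offtake(config, state, outdir, seed, manifest):
    landscape = state["landscape"]
    apps = derive_apps(landscape.population, landscape.urban_mask, landscape.boundary_mask)
    ratio = state["ratio"]
    ratios = {q: getattr(ratio, q) for q in QUANTILE_KEYS}
    rhps = derive_rhps(apps, ratios)
    caps = {
        t.taxon_id: density_cap_per_cell(t, apps.cell_area)
        for t in state["taxa"] if t.density is not None
    }
    masses = {t.taxon_id: t.body_mass for t in state["taxa"]}
    surface = state["hp_surface"]

    per_quantile = {}
    for q in QUANTILE_KEYS:
        hp_q = getattr(surface, q)
        taxon_hp = taxon_individual_hp(hp_q, state["tsop_stack"].proportions)
        off = individuals_offtake(taxon_hp, rhps[q], caps, annual_days=config.annual_days)
        individuals = {t: o.individuals for t, o in off.items()}
        per_taxon_biomass, overall_biomass = biomass_surfaces(
            individuals, masses, quantiles=(q,)
        )
        per_quantile[q] = {
            "offtake": off,
            "individuals_total": float(sum(g.total() for g in individuals.values())),
            "biomass_total_kg": float(overall_biomass[q].total()),
            "overall_biomass": overall_biomass[q],
            "per_taxon_biomass": {t: d[q] for t, d in per_taxon_biomass.items()},
        }
    state["apps"] = apps
    state["rhps"] = rhps
    state["per_quantile"] = per_quantile


def _stage_edible(config, state, outdir, seed, manifest):
    for q, bundle in state["per_quantile"].items():
        annual_edible = edible_production(bundle["overall_biomass"], config.edible_fraction)
        bundle["edible_annual"] = annual_edible
        bundle["edible_total_kg"] = float(annual_edible.total())
        daily = annual_edible.with_values(
            annual_edible.values / config.annual_days, tag="edible_daily_kg"
        )
        bundle["edible_daily"] = daily


def _stage_per_capita(config, state, outdir, seed, manifest):
    apps = state["apps"]
    for q, bundle in state["per_quantile"].items():
        grid = per_capita_availability(bundle["edible_daily"], apps)
        bundle["per_capita"] = grid
        ok = ~grid.mask
        pop = apps.values[ok]
        bundle["per_capita_mean_g_day"] = (
            float((grid.values[ok] * pop).sum() / pop.sum()) if pop.sum() > 0 else float("nan")
        )


def _stage_nutrition(config, state, outdir, seed, manifest):
    content = mean_nutrient_content(load_default_composition(), seed=seed)
    dri = load_default_dri()
    shares = load_default_shares()
    requirements = requirement_surfaces(state["apps"], shares, dri)
    headline = state["per_quantile"]["q50"]
    surfaces, summary = adequacy_percent(headline["edible_daily"], content, requirements)
    state["adequacy_surfaces"] = surfaces
    state["adequacy_summary"] = summary.sort_values("nutrient").reset_index(drop=True)
    path = outdir / "adequacy.csv"
    state["adequacy_summary"].to_csv(path, index=False, float_format="%.6f")
    manifest["digests"]["adequacy.csv"] = _sha256(path)


def _stage_report(config, state, outdir, seed, manifest):
    rows = []
    apps_total = state["apps"].total()
    pop_total = state["landscape"].population.total()
    for q, bundle in state["per_quantile"].items():
        edible_kg = bundle["edible_total_kg"]
        area_km2, co2_mt = beef_counterfactual(
            edible_kg, config.beef_yield_kg_per_ha_day, config.emission_t_per_km2
        )
        row = {
            "quantile": q,
            "hunters_total": state["rhps"][q].total(),
            "annual_individuals": bundle["individuals_total"],
            "annual_biomass_kg": bundle["biomass_total_kg"],
            "annual_edible_kg": edible_kg,
            "per_capita_g_day": bundle["per_capita_mean_g_day"],
            "beef_pasture_km2": area_km2,
            "beef_co2_mt": co2_mt,
        }
        if config.beef_price_per_kg is not None:
            row["edible_value_usd"] = edible_kg * config.beef_price_per_kg
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.insert(1, "apps_total", apps_total)
    summary.insert(2, "population_total", pop_total)

    taxon_rows = []
    headline = state["per_quantile"]["q50"]
    boundary_n = int(state["landscape"].boundary_mask.sum())
    for t in state["taxa"]:
        off = headline["offtake"][t.taxon_id]
        taxon_rows.append({
            "taxon_id": t.taxon_id,
            "annual_individuals": off.individuals.total(),
            "annual_biomass_kg": headline["per_taxon_biomass"][t.taxon_id].total(),
            "pct_cells_truncated": 100.0 * float(off.truncated.sum()) / boundary_n,
            "modelled": bool(state["tsop_modelled"][t.taxon_id]),
        })
    taxon_summary = pd.DataFrame(taxon_rows)

    for name, df in (("summary.csv", summary), ("taxon_summary.csv", taxon_summary)):
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.6f")
        manifest["digests"][name] = _sha256(path)
    state["summary"] = summary
    state["taxon_summary"] = taxon_summary
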