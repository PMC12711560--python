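"""Offtake accounting: from harvest-rate surfaces to extraction, meat and CO2.

Annual offtake per cell is harvest productivity (individuals per hunter per
day) x resident hunters x 365, split across taxa by the composition stack
and bounded above, for taxa with density data, by the standing density of
one cell (individuals per 100 km^2). Biomass follows by body mass, edible
meat by carcass yield, per-capita availability by the rural population, and
a beef-replacement counterfactual converts edible production into the
pasture area and CO2 emissions that producing it from cattle would entail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import TraitError
from .grids import Grid, require_aligned
from .records import MetricEstimate, TaxonProfile

ANNUAL_DAYS = 365
#: Headline edible fraction of undressed carcass biomass.
EDIBLE_FRACTION = 0.585
#: Group-specific edible yields (mean), used by the per-group path.
GROUP_EDIBLE_YIELDS = {"mammal": 0.63, "bird": 0.73, "chelonian": 0.47, "caiman": 0.45}
#: CO2 emitted per km^2 of deforested land converted to pasture (tonnes).
EMISSION_T_PER_KM2 = 18_000.0

MASS_QUANTILES = ("q10", "q25", "q50", "q75", "q90")


def taxon_individual_hp(
    overall_hp: Grid, tsop_proportions: Mapping[str, Grid]
) -> dict[str, Grid]:
    """Split the overall harvest-rate surface across taxa by composition.

    Cellwise product of the overall HP grid with each taxon's proportion
    grid; because the proportions sum to one on valid cells, the per-taxon
    surfaces sum back to the overall surface there.
    """
    out = {}
    for taxon, prop in tsop_proportions.items():
        require_aligned(overall_hp, prop)
        values = np.where(prop.mask, 0.0, overall_hp.values * prop.values)
        out[taxon] = Grid(values, prop.mask.copy(), overall_hp.cell_area, f"hp_{taxon}")
    return out


@dataclass
class TaxonOfftake:
    """Annual per-taxon extraction with the density-cap audit trail."""

    individuals: Grid
    uncapped: Grid
    truncated: np.ndarray  # bool per cell: cap was binding


def individuals_offtake(
    taxon_hp: Mapping[str, Grid],
    rhps: Grid,
    density_caps: Mapping[str, float] | None = None,
    annual_days: int = ANNUAL_DAYS,
) -> dict[str, TaxonOfftake]:
    """Annual individuals extracted per taxon per cell, density-capped.

    offtake = HP (individuals per hunter-day) x hunters in the cell x 365.
    For taxa with an average-density estimate the per-cell annual take is
    truncated at the standing density of one cell (individuals per 100 km^2
    on a 100 km^2 cell); cells where the cap binds are flagged.
    """
    density_caps = density_caps or {}
    out = {}
    for taxon, hp in taxon_hp.items():
        require_aligned(hp, rhps)
        if (hp.values[~hp.mask] < 0).any() or (rhps.values[~rhps.mask] < 0).any():
            raise ValueError("negative harvest rate or hunter count")
        raw = hp.values * rhps.values * annual_days
        raw = np.where(hp.mask | rhps.mask, 0.0, raw)
        cap = density_caps.get(taxon)
        if cap is not None:
            capped = np.minimum(raw, cap)
            truncated = (raw > cap) & ~hp.mask
        else:
            capped = raw
            truncated = np.zeros(hp.shape, dtype=bool)
        out[taxon] = TaxonOfftake(
            individuals=Grid(capped, hp.mask.copy(), hp.cell_area, f"offtake_{taxon}"),
            uncapped=Grid(raw, hp.mask.copy(), hp.cell_area, f"offtake_raw_{taxon}"),
            truncated=truncated,
        )
    return out


def density_cap_per_cell(profile: TaxonProfile, cell_area: float = 100.0) -> float | None:
    """Cap on annual per-cell take: mean standing density scaled to cell area."""
    if profile.density is None:
        return None
    return profile.density.mean * (cell_area / 100.0)


def biomass_surfaces(
    individual_grids: Mapping[str, Grid],
    body_masses: Mapping[str, MetricEstimate],
    quantiles: Sequence[str] = MASS_QUANTILES,
) -> tuple[dict[str, dict[str, Grid]], dict[str, Grid]]:
    """Biomass (kg) per taxon and mass quantile, plus overall per quantile.

    Each taxon's individuals grid is scaled by its body-mass quantile
    (median q50 is the headline); summing over taxa gives the overall
    biomass surface for each quantile. Uncertainty is propagated
    quantile-by-quantile (q10 with q10, ...), never mixing quantile levels.
    """
    per_taxon: dict[str, dict[str, Grid]] = {}
    overall: dict[str, np.ndarray] = {q: None for q in quantiles}
    template = None
    for taxon, grid in individual_grids.items():
        if taxon not in body_masses:
            raise TraitError(f"no body-mass estimate for taxon {taxon!r}")
        mass = body_masses[taxon]
        per_taxon[taxon] = {}
        for q in quantiles:
            m = getattr(mass, q)
            vals = grid.values * m
            per_taxon[taxon][q] = Grid(vals, grid.mask.copy(), grid.cell_area,
                                       f"biomass_{taxon}_{q}")
            overall[q] = vals.copy() if overall[q] is None else overall[q] + vals
        template = grid
    overall_grids = {
        q: Grid(v, template.mask.copy(), template.cell_area, f"biomass_overall_{q}")
        for q, v in overall.items()
    }
    return per_taxon, overall_grids


def edible_production(
    biomass: Grid,
    edible_fraction: float = EDIBLE_FRACTION,
) -> Grid:
    """Edible meat from undressed biomass via the pooled yield (default 0.585)."""
    if not 0.0 < edible_fraction <= 1.0:
        raise ValueError(f"edible_fraction {edible_fraction} outside (0, 1]")
    return biomass.with_values(biomass.values * edible_fraction, tag="edible")


def edible_production_by_group(
    per_taxon_biomass: Mapping[str, Grid],
    groups: Mapping[str, str],
    yields: Mapping[str, float] | None = None,
) -> Grid:
    """Edible meat summing per-taxon biomass scaled by group-specific yields.

    The alternative to the pooled 0.585 factor: mammals 0.63, birds 0.73,
    chelonians 0.47, caimans 0.45. Unknown groups fall back to the pooled
    factor.
    """
    yields = dict(GROUP_EDIBLE_YIELDS if yields is None else yields)
    total = None
    template = None
    for taxon, grid in per_taxon_biomass.items():
        y = yields.get(groups.get(taxon, ""), EDIBLE_FRACTION)
        vals = grid.values * y
        total = vals if total is None else total + vals
        template = grid
    if template is None:
        raise ValueError("no biomass surfaces supplied")
    return Grid(total, template.mask.copy(), template.cell_area, "edible_by_group")


def per_capita_availability(edible_daily_kg: Grid, apps: Grid) -> Grid:
    """Grams of edible meat per rural inhabitant per day.

    Cells with no rural population are masked, not zero: availability per
    person is undefined where there is no one to feed.
    """
    require_aligned(edible_daily_kg, apps)
    pop = apps.values
    mask = edible_daily_kg.mask | apps.mask | (pop <= 0)
    values = np.zeros(apps.shape)
    ok = ~mask
    values[ok] = edible_daily_kg.values[ok] * 1000.0 / pop[ok]
    return Grid(values, mask, apps.cell_area, "per_capita_g_day")


def beef_counterfactual(
    annual_edible_kg: float,
    yield_kg_per_ha_day: float,
    emission_t_per_km2: float = EMISSION_T_PER_KM2,
) -> tuple[float, float]:
    """Pasture area (km^2) and CO2 (Mt) to replace the edible production with beef.

    area = kg / (yield x 365 x 100 ha/km^2); CO2 follows at the deforestation
    emission factor (default 18,000 t per km^2).
    """
    if yield_kg_per_ha_day <= 0:
        raise ValueError("pasture yield must be positive")
    area_km2 = annual_edible_kg / (yield_kg_per_ha_day * ANNUAL_DAYS * 100.0)
    co2_mt = area_km2 * emission_t_per_km2 / 1e6
    return area_km2, co2_mt
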