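"""Nutrient supply from wild meat versus population dietary requirements.

Edible-meat surfaces are converted to per-nutrient daily supply using the
average composition of wild meat (content per 100 g), and compared cellwise
against minimum daily requirements built from dietary reference intakes
(DRIs): per sex-age group (children, women, men) the preferred reference is
the estimated average requirement (EAR), falling back to adequate intake
(AI) or recommended dietary allowance (RDA), the acceptable macronutrient
distribution range midpoint for total fat, and the estimated energy
requirement (EER) for energy. Requirement surfaces are proportional to the
rural population, so adequacy percentages are scale-free in population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DRITableError
from .grids import Grid, require_aligned
from .records import MetricEstimate, monte_carlo_metric

GROUPS = ("children", "women", "men")
DRI_RULES = ("EAR", "AI", "RDA", "AMDR-midpoint", "EER")


def _load_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("wildmeat.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_default_dri() -> pd.DataFrame:
    """Packaged DRI table: one row per (group, nutrient) with value and rule."""
    return _load_packaged_csv("dri_reference.csv")


def load_default_shares() -> "DemographicShares":
    df = _load_packaged_csv("demographic_shares.csv")
    shares = dict(zip(df["group"], df["share"]))
    return DemographicShares(**{g: float(shares[g]) for g in GROUPS})


def load_default_composition() -> pd.DataFrame:
    """Packaged synthetic wild-meat composition observations (per 100 g)."""
    return _load_packaged_csv("nutrient_composition_synthetic.csv")


@dataclass(frozen=True)
class DemographicShares:
    """Proportions of children, women and men in the rural population."""

    children: float
    women: float
    men: float

    def __post_init__(self) -> None:
        vals = (self.children, self.women, self.men)
        if any(v < 0 for v in vals):
            raise ValueError("shares must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"shares must sum to 1, got {sum(vals)}")

    def as_dict(self) -> dict[str, float]:
        return {"children": self.children, "women": self.women, "men": self.men}


def mean_nutrient_content(
    observations: pd.DataFrame,
    n_draws: int = 1000,
    seed: int | None = None,
) -> dict[str, MetricEstimate]:
    """Pooled per-nutrient content of wild meat (per 100 g edible meat).

    ``observations`` has one row per literature observation with columns
    ``nutrient``, ``value`` and a mandatory ``unit`` column (units are not
    assumed). The mean is propagated through the 1,000-draw Monte Carlo with
    se = sd/sqrt(n); nutrients with no observations are skipped with a
    warning. Taxa without their own data inherit these pooled (food-matched)
    values.
    """
    if "unit" not in observations.columns:
        raise ValueError("observation table must carry a 'unit' column")
    rng = np.random.default_rng(seed)
    out: dict[str, MetricEstimate] = {}
    for nutrient, sub in observations.groupby("nutrient", sort=True):
        vals = sub["value"].to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"nutrient {nutrient!r} has no observations; excluded",
                          stacklevel=2)
            continue
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out[str(nutrient)] = monte_carlo_metric(
            float(vals.mean()), se, n_draws=n_draws, seed=rng, positive=True
        )
    return out


def taxon_nutrient_profiles(
    observations: pd.DataFrame,
    taxon_groups: Mapping[str, str],
    n_draws: int = 1000,
    seed: int | None = None,
) -> dict[str, dict[str, MetricEstimate]]:
    """Per-taxon nutrient profiles with food-matching fallbacks.

    A taxon with its own composition observations uses them; a taxon without
    data inherits the mean of its taxonomic group; a taxon whose group has no
    data falls back to the pooled wild-meat mean. This mirrors the
    food-matching practice used when species-specific composition tables are
    sparse.
    """
    rng = np.random.default_rng(seed)
    pooled = mean_nutrient_content(observations, n_draws=n_draws, seed=rng)
    by_group: dict[str, dict[str, MetricEstimate]] = {}
    obs_groups = observations.assign(
        _group=observations["taxon_id"].map(dict(taxon_groups))
    )
    for group, sub in obs_groups.dropna(subset=["_group"]).groupby("_group"):
        by_group[str(group)] = mean_nutrient_content(sub, n_draws=n_draws, seed=rng)
    out: dict[str, dict[str, MetricEstimate]] = {}
    for taxon, group in taxon_groups.items():
        # pooled mean < group mean < taxon's own data, nutrient by nutrient
        profile = dict(pooled)
        profile.update(by_group.get(group, {}))
        own = observations[observations["taxon_id"] == taxon]
        if len(own):
            profile.update(mean_nutrient_content(own, n_draws=n_draws, seed=rng))
        out[taxon] = profile
    return out


def requirement_surfaces(
    apps: Grid,
    shares: DemographicShares,
    dri: pd.DataFrame,
    nutrients: list[str] | None = None,
) -> dict[str, Grid]:
    """Per-nutrient minimum daily requirement grids.

    The rural-population grid is split into sex-age group grids by the
    demographic shares; each group grid times its per-person reference value
    gives a group requirement surface, and the groups sum to the overall
    requirement. Requirements are exactly proportional to population, so an
    empty cell needs nothing. Missing (group, nutrient) entries raise,
    naming the hole.
    """
    dri = dri.set_index(["group", "nutrient"]) if not isinstance(dri.index, pd.MultiIndex) else dri
    if nutrients is None:
        nutrients = sorted({n for (_, n) in dri.index})
    out: dict[str, Grid] = {}
    for nutrient in nutrients:
        per_person = {}
        for group, share in shares.as_dict().items():
            key = (group, nutrient)
            if key not in dri.index:
                raise DRITableError(f"no DRI entry for group={group!r}, nutrient={nutrient!r}")
            per_person[group] = float(dri.loc[key, "value"]) * share
        factor = sum(per_person.values())
        values = np.where(apps.mask, 0.0, apps.values * factor)
        out[nutrient] = Grid(values, apps.mask.copy(), apps.cell_area, f"requirement_{nutrient}")
    return out


def adequacy_percent(
    edible_daily_kg: Grid,
    nutrient_content: Mapping[str, MetricEstimate | float],
    requirements: Mapping[str, Grid],
) -> tuple[dict[str, Grid], pd.DataFrame]:
    """Percent of daily requirements met by wild meat, per nutrient per cell.

    supplied = edible grams/day x content per 100 g / 100;
    percent = 100 x supplied / required, masked where the requirement is
    zero (no population). The summary row per nutrient is the
    requirement-weighted aggregate, 100 x total supplied / total required,
    which equals the population-weighted mean adequacy.
    """
    surfaces: dict[str, Grid] = {}
    rows = []
    for nutrient, req in requirements.items():
        content = nutrient_content.get(nutrient)
        if content is None:
            continue
        per100 = content.mean if isinstance(content, MetricEstimate) else float(content)
        require_aligned(edible_daily_kg, req)
        supplied = edible_daily_kg.values * 1000.0 * per100 / 100.0
        mask = edible_daily_kg.mask | req.mask | (req.values <= 0)
        pct = np.zeros(req.shape)
        ok = ~mask
        pct[ok] = 100.0 * supplied[ok] / req.values[ok]
        surfaces[nutrient] = Grid(pct, mask, req.cell_area, f"adequacy_{nutrient}")
        total_req = req.values[ok].sum()
        summary = 100.0 * supplied[ok].sum() / total_req if total_req > 0 else np.nan
        rows.append({"nutrient": nutrient, "adequacy_pct": summary,
                     "content_per_100g": per100})
    return surfaces, pd.DataFrame(rows)
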