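"""Self-contained synthetic landscapes, taxa, communities and hunting records.

The real hunting dataset this pipeline was designed around is not publicly
distributable (locality-level hunting records are sensitive), so every stage
can instead be exercised on synthetic inputs with known ground truth. The
generator emulates the statistical structure the analysis assumes:

* covariate layers that are spatially autocorrelated (Gaussian-smoothed white
  noise), including >= 2 categorical layers (language family, urban-rural
  catchment class) and time-varying habitat-loss / greenness snapshots;
* a true harvest-productivity surface that is a known monotone function of a
  small number of covariates plus categorical offsets, so recovery tests have
  an unambiguous answer;
* log-normal body masses spanning several orders of magnitude, blob-shaped
  contiguous taxon ranges, per-cell taxon-composition ground truth summing
  to one over in-range taxa;
* per-locality Poisson harvest counts driven by the true rate, multinomial
  taxon splits restricted to in-range taxa, binomial hunters given consumers
  with a hunters-to-consumers ratio near the published 0.178.

Everything is driven by a single integer seed and is bit-reproducible.
Realistic geography, hunter behaviour and seasonality are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .errors import ConfigurationError, PlacementError
from .grids import Grid, GridStack
from .records import (
    MetricEstimate,
    TaxonProfile,
    UNDETERMINED,
    monte_carlo_metric,
    summarize_traits,
)

EDIBLE_GROUPS = ("mammal", "bird", "chelonian", "caiman")

#: Nutrients carried on synthetic profiles, with per-100 g base levels typical
#: of game meat (energy kcal, protein/fat g, iron/zinc/B1-B3 mg, Se/B12 ug).
_NUTRIENT_BASE = {
    "energy": 120.0, "protein": 21.0, "total_fat": 3.0,
    "iron": 3.5, "zinc": 3.0, "selenium": 10.0,
    "vitamin_b1": 0.10, "vitamin_b2": 0.25, "vitamin_b3": 5.0, "vitamin_b12": 2.0,
}


@dataclass
class LandscapeConfig:
    """Dimensions and knobs of a synthetic landscape.

    ``n_covariates`` counts distinct covariate layers (the analysis this
    emulates used 12); ``urban_fraction`` is the proportion of inside-boundary
    cells flagged urban; ``deforestation_max`` scales the habitat-loss field
    (0 gives an all-zero layer). ``smooth_sigma`` is the Gaussian-blur range
    of the autocorrelated fields, in cells.
    """

    n_rows: int = 40
    n_cols: int = 40
    n_covariates: int = 12
    urban_fraction: float = 0.03
    deforestation_max: float = 0.6
    smooth_sigma: float = 3.0
    population_mean: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_rows < 4 or self.n_cols < 4:
            problems.append(f"grid must be at least 4x4, got {self.n_rows}x{self.n_cols}")
        if not 0.0 <= self.urban_fraction < 1.0:
            problems.append(f"urban_fraction {self.urban_fraction} outside [0, 1)")
        if self.n_covariates < 4:
            problems.append("need at least 4 covariates (2 continuous + 2 categorical)")
        if not 0.0 <= self.deforestation_max <= 1.0:
            problems.append(f"deforestation_max {self.deforestation_max} outside [0, 1]")
        if problems:
            raise ConfigurationError("; ".join(problems))


@dataclass
class Landscape:
    """A generated landscape: covariate stack, masks, population, truth inputs."""

    stack: GridStack
    population: Grid
    urban_mask: np.ndarray
    boundary_mask: np.ndarray
    true_hp: np.ndarray  # expected individuals per hunter-day per cell
    config: LandscapeConfig

    @property
    def shape(self) -> tuple[int, int]:
        return self.boundary_mask.shape


@dataclass
class GroundTruth:
    """Known generating quantities, returned for recovery tests.

    ``true_tsop_surface`` is (n_taxa, rows, cols); on every inside-boundary
    cell the in-range taxon proportions sum to 1.
    """

    true_hp_surface: np.ndarray
    true_tsop_surface: np.ndarray
    true_hunter_ratio: float
    taxon_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.true_hp_surface < 0).any():
            raise ValueError("true_hp_surface must be non-negative")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized spatially autocorrelated field (blurred white noise)."""
    raw = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma, mode="nearest")
    return (raw - raw.mean()) / (raw.std() + 1e-12)


def _categorical_field(rng: np.random.Generator, shape, n_levels: int, sigma: float) -> np.ndarray:
    """Contiguous categorical patches: argmax over smoothed noise fields."""
    fields = np.stack([_smooth_field(rng, shape, sigma) for _ in range(n_levels)])
    return np.argmax(fields, axis=0)


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Build the covariate stack, masks, population grid and true HP surface.

    The true harvest rate is a monotone function of greenness (EVI, the
    designated driver), depressed by habitat loss and flood proportion, with
    additive offsets per language-family patch — a known answer for
    variable-importance and recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    nr, nc = config.n_rows, config.n_cols
    shape = (nr, nc)
    sigma = config.smooth_sigma

    # Elliptical study boundary covering most of the lattice.
    rr, cc = np.mgrid[0:nr, 0:nc]
    boundary = (
        ((rr - (nr - 1) / 2) / (0.55 * nr)) ** 2
        + ((cc - (nc - 1) / 2) / (0.55 * nc)) ** 2
    ) <= 1.0
    outside = ~boundary

    epochs_hl = tuple(range(1985, 2021, 5))
    epochs_evi = tuple(range(2000, 2021, 5))

    evi_base = _smooth_field(rng, shape, sigma)
    evi_snaps = {}
    for i, ep in enumerate(epochs_evi):
        drift = 0.05 * i * _smooth_field(rng, shape, sigma)
        evi_snaps[ep] = Grid(evi_base + drift, outside.copy(), tag=f"evi_{ep}")

    loss_base = expit(2.0 * _smooth_field(rng, shape, sigma))
    loss_snaps = {}
    for i, ep in enumerate(epochs_hl):
        ramp = (i + 1) / len(epochs_hl)
        loss_snaps[ep] = Grid(
            config.deforestation_max * ramp * loss_base, outside.copy(),
            tag=f"habitat_loss_{ep}",
        )

    static_names = ["gpp", "npp", "soil_fertility", "flooded_prop", "elevation", "hand"]
    n_generic = max(0, config.n_covariates - (2 + len(static_names) + 3))
    static_names += [f"aux_{k + 1}" for k in range(n_generic)]
    # Trim generic/static tail if fewer covariates were requested; EVI,
    # habitat loss and the categorical layers are always present.
    keep = max(0, config.n_covariates - 5)
    static_names = static_names[:keep] if keep < len(static_names) else static_names

    static: dict[str, Grid] = {}
    for name in static_names:
        fld = _smooth_field(rng, shape, sigma)
        if name == "flooded_prop":
            fld = expit(1.5 * fld)
        static[name] = Grid(fld, outside.copy(), tag=name)
    flooded = static.get("flooded_prop", Grid(np.zeros(shape), outside.copy())).values

    lang = _categorical_field(rng, shape, 4, 2 * sigma)
    urca = _categorical_field(rng, shape, 5, 2 * sigma)
    indig = (_smooth_field(rng, shape, 2 * sigma) > 0).astype(int)
    static["language_family"] = Grid(lang.astype(float), outside.copy(), tag="language_family")
    static["urca_class"] = Grid(urca.astype(float), outside.copy(), tag="urca_class")
    static["indigenous_land"] = Grid(indig.astype(float), outside.copy(), tag="indigenous_land")
    levels = {
        "language_family": {i: f"family_{i}" for i in range(4)},
        "urca_class": {i: f"urca_{i}" for i in range(5)},
        "indigenous_land": {0: "outside", 1: "inside"},
    }

    stack = GridStack(
        static=static,
        temporal={"evi": evi_snaps, "habitat_loss": loss_snaps},
        levels=levels,
    )

    # Population: log-normal spatial intensity, clustered.
    pop_field = np.exp(0.8 * _smooth_field(rng, shape, sigma))
    population = config.population_mean * pop_field / pop_field[boundary].mean()
    population = np.where(boundary, population, 0.0)
    pop_grid = Grid(population, outside.copy(), tag="population")

    # Urban mask: the highest-population inside cells.
    urban = np.zeros(shape, dtype=bool)
    n_urban = int(round(config.urban_fraction * boundary.sum()))
    if n_urban > 0:
        inside_idx = np.flatnonzero(boundary.ravel())
        order = np.argsort(population.ravel()[inside_idx])[::-1]
        urban.ravel()[inside_idx[order[:n_urban]]] = True

    # truth is defined on the latest-epoch covariates: that is the state of
    # the landscape any prediction surface is evaluated against
    loss_now = loss_snaps[epochs_hl[-1]].values
    evi_now = evi_snaps[epochs_evi[-1]].values
    true_hp = (
        0.02
        + 0.10 * expit(2.0 * evi_now)
        - 0.05 * loss_now
        - 0.015 * expit(1.5 * (flooded - 0.5))
        + 0.006 * lang
    )
    true_hp = np.clip(np.where(boundary, true_hp, 0.0), 0.0, None)

    return Landscape(stack, pop_grid, urban, boundary, true_hp, config)


def generate_taxa(
    n_taxa: int,
    shape: tuple[int, int],
    boundary_mask: np.ndarray,
    seed: int = 0,
    mass_median_kg: float = 2.0,
    mass_sigma_log: float = 2.3,
    mass_range: tuple[float, float] | None = None,
    density_fraction: float = 0.8,
    n_mass_obs: int = 5,
    obs_noise_sd: float = 0.10,
) -> tuple[list[TaxonProfile], dict[str, np.ndarray], pd.DataFrame]:
    """Draw taxon profiles, blob ranges and a trait observation table.

    Body masses are log-normal (default ln-sd 2.3, i.e. the pool spans several
    orders of magnitude, as the real hunted-taxon pool does); a degenerate
    ``mass_range=(m, m)`` pins every mass at ``m``. Densities (individuals per
    100 km^2) are log-normal and assigned to ``density_fraction`` of taxa —
    only those can later be density-capped. Each taxon gets a contiguous
    disk-shaped range covering at least 10% of inside-boundary cells; the
    first taxon is a generalist covering the whole boundary, so every cell has
    at least one in-range taxon. Returns (profiles, range masks, mass
    observation table with one row per observation).
    """
    if n_taxa < 2:
        raise ConfigurationError(f"need at least 2 taxa, got {n_taxa}")
    rng = np.random.default_rng(seed)
    nr, nc = shape
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    inside = np.argwhere(boundary_mask)
    n_inside = len(inside)
    if n_inside == 0:
        raise PlacementError("boundary mask has no inside cells")

    if mass_range is not None:
        lo, hi = mass_range
        true_masses = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_taxa))
    else:
        true_masses = np.exp(rng.normal(np.log(mass_median_kg), mass_sigma_log, size=n_taxa))

    obs_rows = []
    for i, m in enumerate(true_masses):
        n_obs = max(1, n_mass_obs + int(rng.integers(-2, 3)))
        obs = m * np.exp(rng.normal(0.0, obs_noise_sd, size=n_obs))
        for v in obs:
            obs_rows.append({"taxon_id": f"taxon_{i:03d}", "trait": "body_mass",
                             "value": float(v), "unit": "kg"})
    mass_obs = pd.DataFrame(obs_rows)
    mass_summaries = summarize_traits(mass_obs, seed=int(rng.integers(2**31)))

    densities = np.exp(rng.normal(np.log(200.0), 1.0, size=n_taxa))
    has_density = rng.random(n_taxa) < density_fraction
    has_density[0] = True

    rr, cc = np.mgrid[0:nr, 0:nc]
    ranges: dict[str, np.ndarray] = {}
    profiles: list[TaxonProfile] = []
    min_cells = max(1, int(np.ceil(0.10 * n_inside)))
    for i in range(n_taxa):
        tid = f"taxon_{i:03d}"
        if i == 0:
            mask = boundary_mask.copy()  # generalist: full coverage
        else:
            centre = inside[rng.integers(n_inside)]
            radius = rng.uniform(0.25, 0.6) * min(nr, nc)
            for _ in range(50):
                disk = ((rr - centre[0]) ** 2 + (cc - centre[1]) ** 2) <= radius**2
                mask = disk & boundary_mask
                if mask.sum() >= min_cells:
                    break
                radius *= 1.3
        ranges[tid] = mask
        group = EDIBLE_GROUPS[int(rng.integers(len(EDIBLE_GROUPS)))]
        nutrients = {
            k: float(max(0.0, v * np.exp(rng.normal(0.0, 0.15))))
            for k, v in _NUTRIENT_BASE.items()
        }
        dens = None
        if has_density[i]:
            dens = monte_carlo_like(densities[i], 0.15 * densities[i], rng)
        profiles.append(
            TaxonProfile(
                taxon_id=tid,
                body_mass=mass_summaries[tid],
                density=dens,
                edible_group=group,
                nutrient_profile=nutrients,
            )
        )
    return profiles, ranges, mass_obs


def monte_carlo_like(mean: float, se: float, rng: np.random.Generator,
                     n_draws: int = 1000) -> MetricEstimate:
    """MetricEstimate from positive normal draws (thin wrapper, shared rng)."""
    return monte_carlo_metric(mean, se, n_draws=n_draws, seed=rng, positive=True)


def generate_communities(
    landscape: Landscape,
    n_localities: int,
    true_hunter_ratio: float = 0.178,
    seed: int = 0,
    consumers_mean: float = 120.0,
) -> pd.DataFrame:
    """Place hunting communities on rural (non-urban, inside-boundary) cells.

    Consumers per locality are Poisson around ``consumers_mean`` (with a
    floor of 10) and hunters are Binomial(consumers, true ratio), so the
    pooled hunters-to-consumers ratio concentrates on the truth.
    """
    rng = np.random.default_rng(seed)
    eligible = np.argwhere(landscape.boundary_mask & ~landscape.urban_mask)
    if len(eligible) < n_localities:
        raise PlacementError(
            f"{n_localities} localities requested but only {len(eligible)} eligible cells"
        )
    if not 0.0 <= true_hunter_ratio <= 1.0:
        raise ConfigurationError(f"true_hunter_ratio {true_hunter_ratio} outside [0, 1]")
    picks = eligible[rng.choice(len(eligible), size=n_localities, replace=False)]
    consumers = 10 + rng.poisson(max(consumers_mean - 10, 0), size=n_localities)
    hunters = rng.binomial(consumers, true_hunter_ratio)
    return pd.DataFrame(
        {
            "locality_id": [f"loc_{i:04d}" for i in range(n_localities)],
            "row": picks[:, 0],
            "col": picks[:, 1],
            "n_consumers": consumers,
            "n_hunters": hunters,
        }
    )


def build_ground_truth(
    landscape: Landscape,
    taxa: Sequence[TaxonProfile],
    ranges: dict[str, np.ndarray],
    true_hunter_ratio: float = 0.178,
    seed: int = 0,
    evi_affinity_scale: float = 1.5,
) -> GroundTruth:
    """Per-cell true composition: softmax taxon affinities clipped to ranges.

    Each taxon's log-affinity is an intercept plus a slope on the greenness
    field, so composition varies smoothly in space; out-of-range taxa get
    zero weight and the remainder renormalizes to sum to one per cell.
    """
    rng = np.random.default_rng(seed)
    nr, nc = landscape.shape
    n_taxa = len(taxa)
    evi = landscape.stack.temporal["evi"][max(landscape.stack.temporal["evi"])].values
    intercepts = rng.normal(0.0, 1.0, size=n_taxa)
    slopes = rng.normal(0.0, evi_affinity_scale, size=n_taxa)
    logw = intercepts[:, None, None] + slopes[:, None, None] * evi[None, :, :]
    w = np.exp(logw - logw.max(axis=0, keepdims=True))
    for i, t in enumerate(taxa):
        w[i][~ranges[t.taxon_id]] = 0.0
    total = w.sum(axis=0)
    tsop = np.zeros_like(w)
    ok = total > 0
    tsop[:, ok] = w[:, ok] / total[ok]
    tsop[:, ~landscape.boundary_mask] = 0.0
    return GroundTruth(
        true_hp_surface=landscape.true_hp,
        true_tsop_surface=tsop,
        true_hunter_ratio=float(true_hunter_ratio),
        taxon_ids=tuple(t.taxon_id for t in taxa),
    )


def generate_hunting_records(
    localities: pd.DataFrame,
    ground_truth: GroundTruth,
    effort_days: int | tuple[int, int] = (60, 400),
    seed: int = 0,
    year_range: tuple[int, int] = (1995, 2020),
    undetermined_fraction: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the hunting-record and study-effort tables.

    Per locality: a recording span is drawn uniformly over ``effort_days``
    (or fixed, if a scalar is given); total kills are Poisson with mean
    true_hp x hunters x span; each kill's taxon is multinomial over the true
    cell composition (already restricted to in-range taxa); optionally a
    fraction of kills is relabelled ``undetermined``. Returns
    ``(records, efforts)`` in the external CSV schemas.
    """
    boundary_ok = ground_truth.true_tsop_surface.sum(axis=0) > 0
    if isinstance(effort_days, tuple):
        lo, hi = effort_days
    else:
        lo = hi = int(effort_days)
    if lo < 1:
        raise ConfigurationError("effort_days must be >= 1")

    rec_rows, eff_rows = [], []
    taxon_ids = np.array(ground_truth.taxon_ids)
    for i, loc in enumerate(localities.itertuples(index=False)):
        # independent substream per locality: optional extras (e.g. the
        # undetermined relabelling) never perturb other localities' draws
        rng = np.random.default_rng([int(seed), i])
        r, c = int(loc.row), int(loc.col)
        if not boundary_ok[r, c] and ground_truth.true_hp_surface[r, c] > 0:
            raise PlacementError(f"locality {loc.locality_id!r} outside the modelled boundary")
        span = int(rng.integers(lo, hi + 1))
        year = int(rng.integers(year_range[0], year_range[1] + 1))
        mean_kills = ground_truth.true_hp_surface[r, c] * loc.n_hunters * span
        total = int(rng.poisson(mean_kills))
        eff_rows.append({"locality_id": loc.locality_id, "n_hunters": int(loc.n_hunters),
                         "span_days": span, "year": year})
        if total == 0:
            continue
        p = ground_truth.true_tsop_surface[:, r, c]
        if p.sum() <= 0:
            continue
        counts = rng.multinomial(total, p / p.sum())
        n_und = 0
        if undetermined_fraction > 0:
            # each kill is independently left unidentified with prob f;
            # totals are conserved exactly
            und = rng.binomial(counts, undetermined_fraction)
            counts = counts - und
            n_und = int(und.sum())
        for tid, n in zip(taxon_ids, counts):
            if n > 0:
                rec_rows.append({"locality_id": loc.locality_id, "year": year,
                                 "taxon_id": tid, "n_individuals": int(n)})
        if n_und > 0:
            rec_rows.append({"locality_id": loc.locality_id, "year": year,
                             "taxon_id": UNDETERMINED, "n_individuals": n_und})
    records = pd.DataFrame(rec_rows, columns=["locality_id", "year", "taxon_id", "n_individuals"])
    efforts = pd.DataFrame(eff_rows, columns=["locality_id", "n_hunters", "span_days", "year"])
    return records, efforts
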