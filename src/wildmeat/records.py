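"""Hunting-record harmonization and locality-level harvest metrics.

The core quantities are the hunter harvest rate (HHR: animals hunted per
hunter per day at a locality, with the denominator counting all monitored
hunter-days including days with no harvest) and the taxon-specific offtake
proportion (TSOP: the fraction of a locality's total harvest belonging to
one taxon). Trait summaries (body mass, density, edible yield, nutrient
content) are propagated with a 1,000-draw normal Monte Carlo, reported as
mean, standard deviation and the 10/25/50/75/90% quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EffortError, ReclassificationError, UndefinedTSOPError

#: Reserved label for harvest records that could not be assigned to a taxon.
UNDETERMINED = "undetermined"

#: Published hunters-to-consumers ratio quantiles (median and the
#: 0.10/0.25/0.75/0.90 quantiles across 72 localities reporting both counts),
#: used when no locality-level counts are supplied.
DEFAULT_HUNTER_RATIO_QUANTILES = {
    "q10": 0.168,
    "q25": 0.173,
    "q50": 0.178,
    "q75": 0.183,
    "q90": 0.187,
}

_Z90 = 1.2815515655446004  # standard normal 90% quantile


@dataclass(frozen=True)
class MetricEstimate:
    """Summary of a scalar metric: mean, sd and 10-90% quantiles."""

    mean: float
    sd: float
    q10: float
    q25: float
    q50: float
    q75: float
    q90: float

    def __post_init__(self) -> None:
        qs = (self.q10, self.q25, self.q50, self.q75, self.q90)
        if any(b < a - 1e-12 for a, b in zip(qs, qs[1:])):
            raise ValueError(f"quantiles not sorted: {qs}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_sample(cls, sample: np.ndarray) -> "MetricEstimate":
        sample = np.asarray(sample, dtype=float)
        q = np.quantile(sample, [0.10, 0.25, 0.50, 0.75, 0.90])
        return cls(float(sample.mean()), float(sample.std(ddof=1)) if sample.size > 1 else 0.0,
                   *map(float, q))

    @property
    def ci90(self) -> tuple[float, float]:
        """Normal-theory 90% interval, mean +/- 1.645 sd."""
        half = 1.6448536269514722 * self.sd
        return (self.mean - half, self.mean + half)

    def scaled(self, k: float) -> "MetricEstimate":
        if k < 0:
            raise ValueError("scale factor must be non-negative")
        return MetricEstimate(self.mean * k, self.sd * k, self.q10 * k, self.q25 * k,
                              self.q50 * k, self.q75 * k, self.q90 * k)

    def as_dict(self) -> dict[str, float]:
        return {"mean": self.mean, "sd": self.sd, "q10": self.q10, "q25": self.q25,
                "q50": self.q50, "q75": self.q75, "q90": self.q90}


@dataclass
class TaxonProfile:
    """Trait bundle for one analysis taxon.

    ``density`` is individuals per 100 km^2 and may be absent (only a subset
    of taxa have published density observations; only those are density-capped
    during offtake accounting). ``nutrient_profile`` holds content per 100 g
    of edible meat.
    """

    taxon_id: str
    body_mass: MetricEstimate
    density: MetricEstimate | None = None
    edible_group: str = "mammal"
    nutrient_profile: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.body_mass.mean <= 0:
            raise ValueError(f"taxon {self.taxon_id!r}: body mass must be positive")
        if self.density is not None and self.density.mean <= 0:
            raise ValueError(f"taxon {self.taxon_id!r}: density must be positive")


# ---------------------------------------------------------------------------
# Monte Carlo metric propagation
# ---------------------------------------------------------------------------

def monte_carlo_metric(
    mean: float,
    standard_error: float,
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
    positive: bool = False,
) -> MetricEstimate:
    """Propagate a (mean, standard error) pair through normal Monte Carlo.

    Draws ``n_draws`` values from N(mean, se) and summarizes them. For
    strictly positive quantities (``positive=True``) negative draws are
    rejected and redrawn rather than truncated at zero, which avoids a
    spurious probability atom at 0 in the reported quantiles.
    """
    if standard_error < 0:
        raise ValueError("standard_error must be non-negative")
    if standard_error == 0:
        return MetricEstimate(mean, 0.0, mean, mean, mean, mean, mean)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.normal(mean, standard_error, size=n_draws)
    if positive:
        for _ in range(1000):
            bad = draws < 0
            if not bad.any():
                break
            draws[bad] = rng.normal(mean, standard_error, size=int(bad.sum()))
        else:
            raise ValueError(
                "rejection sampling failed: distribution has almost no positive mass"
            )
    return MetricEstimate.from_sample(draws)


def summarize_traits(
    observations: pd.DataFrame,
    value_col: str = "value",
    by: str = "taxon_id",
    n_draws: int = 1000,
    seed: int | None = None,
    positive: bool = True,
) -> dict[str, MetricEstimate]:
    """Per-taxon Monte Carlo summaries from a one-row-per-observation table.

    The standard error is sd/sqrt(n) over the observations; a taxon with a
    single observation gets se = 0 (a point estimate).
    """
    out: dict[str, MetricEstimate] = {}
    root = np.random.default_rng(seed)
    for key, sub in observations.groupby(by, sort=True):
        vals = sub[value_col].to_numpy(dtype=float)
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out[str(key)] = monte_carlo_metric(
            float(vals.mean()), se, n_draws=n_draws, seed=root, positive=positive
        )
    return out


# ---------------------------------------------------------------------------
# Record harmonization and filters
# ---------------------------------------------------------------------------

def apply_reclassification(
    raw_records: pd.DataFrame, mapping: Mapping[str, str] | pd.DataFrame
) -> pd.DataFrame:
    """Merge raw taxon labels into the analysis taxa, conserving counts.

    ``mapping`` maps every raw label (outdated names, vernacular labels,
    typos, allopatric species lumped to genus) to a registry taxon or the
    reserved ``undetermined`` code. Unmapped labels raise, listing all
    offenders; total individuals are conserved exactly.
    """
    if isinstance(mapping, pd.DataFrame):
        mapping = dict(zip(mapping["raw_label"], mapping["taxon_id"]))
    labels = raw_records["taxon_id"].unique()
    unmapped = sorted(set(labels) - set(mapping))
    if unmapped:
        raise ReclassificationError(f"unmapped taxon labels: {unmapped}")
    out = raw_records.copy()
    out["taxon_id"] = out["taxon_id"].map(mapping)
    keys = [c for c in ("locality_id", "year", "taxon_id") if c in out.columns]
    out = out.groupby(keys, as_index=False)["n_individuals"].sum()
    return out


def filter_studies(
    records: pd.DataFrame,
    efforts: pd.DataFrame,
    min_taxa: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the record-level study filters.

    Localities reporting fewer than ``min_taxa`` distinct determined taxa are
    dropped from both outputs (such studies say little about composition).
    Localities without a usable effort row are additionally dropped from the
    HHR set only — composition (TSOP) does not need effort. Returns
    ``(records_for_tsop, records_for_hhr)``.
    """
    counted = records[records["taxon_id"] != UNDETERMINED]
    n_taxa = counted.groupby("locality_id")["taxon_id"].nunique()
    rich = set(n_taxa[n_taxa >= min_taxa].index)
    tsop_records = records[records["locality_id"].isin(rich)].copy()
    usable = efforts[(efforts["n_hunters"] > 0) & (efforts["span_days"] > 0)]
    with_effort = set(usable["locality_id"])
    hhr_records = tsop_records[tsop_records["locality_id"].isin(with_effort)].copy()
    return tsop_records, hhr_records


def efforts_for(records: pd.DataFrame, efforts: pd.DataFrame) -> pd.DataFrame:
    """Effort rows restricted to the localities present in a record set.

    :func:`compute_hhr` assigns a genuine zero rate to every locality in its
    effort table, so effort rows must be subset to the filtered study set
    first — otherwise localities excluded by the study filters would
    re-enter as spurious zero-harvest labels.
    """
    keep = set(records["locality_id"])
    return efforts[efforts["locality_id"].isin(keep)].copy()


def compute_hhr(records: pd.DataFrame, efforts: pd.DataFrame) -> pd.Series:
    """Per-locality hunter harvest rate (individuals per hunter-day).

    HHR = total individuals of all taxa / total hunter-days, where
    hunter-days = sum over effort rows of n_hunters x span_days. The
    denominator covers the whole monitored span, including days on which no
    hunting or no harvest occurred, so splitting one effort row into several
    with the same total hunter-days leaves HHR unchanged.
    """
    hunter_days = (
        (efforts["n_hunters"] * efforts["span_days"]).groupby(efforts["locality_id"]).sum()
    )
    if (hunter_days <= 0).any():
        bad = hunter_days[hunter_days <= 0].index.tolist()
        raise EffortError(f"non-positive hunter-days for localities {bad}")
    kills = records.groupby("locality_id")["n_individuals"].sum()
    missing = kills.index.difference(hunter_days.index)
    if len(missing):
        raise EffortError(f"no effort rows for localities {sorted(missing)}")
    hhr = kills.reindex(hunter_days.index, fill_value=0) / hunter_days
    hhr.name = "hhr"
    return hhr


def compute_tsop(records: pd.DataFrame) -> pd.DataFrame:
    """Per-locality taxon-specific offtake proportions.

    Rows are localities, columns registry taxa (plus ``undetermined`` when it
    occurs); each row sums to 1. The undetermined bucket stays in the
    denominator — it is real harvest — even though no spatial model is later
    fitted for it. A locality with zero total harvest has no defined
    composition and raises.
    """
    pivot = records.pivot_table(
        index="locality_id", columns="taxon_id", values="n_individuals",
        aggfunc="sum", fill_value=0,
    )
    totals = pivot.sum(axis=1)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise UndefinedTSOPError(f"zero total harvest at localities {bad}")
    return pivot.div(totals, axis=0)


def hunter_consumer_ratio(
    localities: pd.DataFrame | None = None,
    n_draws: int = 1000,
    seed: int | None = None,
) -> MetricEstimate:
    """Hunters-to-consumers ratio summarized across localities.

    With locality data (columns ``n_hunters``, ``n_consumers``) the estimate
    is the median and 10/25/75/90% quantiles of the per-locality ratios;
    localities with zero consumers are excluded with a warning. Without data
    the published constants are used (median 0.178, quantiles 0.168, 0.173,
    0.183, 0.187); the sd is then backed out of the quantile spread,
    (q90 - q10) / (2 z_0.90).
    """
    if localities is None or len(localities) == 0:
        q = DEFAULT_HUNTER_RATIO_QUANTILES
        sd = (q["q90"] - q["q10"]) / (2 * _Z90)
        return MetricEstimate(q["q50"], sd, q["q10"], q["q25"], q["q50"], q["q75"], q["q90"])
    data = localities.copy()
    zero = data["n_consumers"] <= 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} localities with zero consumers", stacklevel=2
        )
        data = data[~zero]
    if len(data) == 0:
        raise EffortError("no locality with positive consumer count")
    ratios = (data["n_hunters"] / data["n_consumers"]).to_numpy(dtype=float)
    return MetricEstimate.from_sample(ratios)
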