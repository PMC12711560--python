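"""Subsampled random-forest ensembles for harvest productivity and composition.

The harvest-rate surface (HP) is predicted by an ensemble of 30 regression
forests, each trained on a seeded 70% subsample of the localities without
replacement. Cellwise 10/25/50/75/90% quantiles across the member
predictions form a :class:`QuantileSurface`; mean, sd and the 90% interval
are then derived from that five-grid stack. Per-taxon offtake proportions
(TSOP) are fitted as single seeded forests on the same covariates minus the
recording-span effort control, clipped to each taxon's range and renormalized
cellwise so the composition sums to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .errors import AlignmentError
from .grids import Grid, GridStack, match_epoch
_Z90 = 1.6448536269514722

SPAN_COVARIATE = "span_days"


@dataclass
class EnsembleSpec:
    """Ensemble hyperparameters.

    30 members on 70% subsamples is the reference configuration; trees per
    member default to 500. Member seeds are ``seed + 1 + index`` so training
    is reproducible end to end.
    """

    n_members: int = 30
    subsample_fraction: float = 0.70
    n_trees: int = 500
    quantiles: tuple[float, ...] = (0.10, 0.25, 0.50, 0.75, 0.90)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if tuple(self.quantiles) != tuple(sorted(self.quantiles)):
            raise ValueError("quantiles must be sorted ascending")
        if self.n_members < 1 or self.n_trees < 1:
            raise ValueError("n_members and n_trees must be positive")


@dataclass
class QuantileSurface:
    """Per-cell quantile grids plus mean/sd/90%-interval derived from them."""

    q10: Grid
    q25: Grid
    q50: Grid
    q75: Grid
    q90: Grid
    mean: Grid
    sd: Grid
    ci_lo: Grid
    ci_hi: Grid

    @classmethod
    def from_member_predictions(
        cls,
        member_preds: np.ndarray,
        template: Grid,
        quantiles: Sequence[float] = (0.10, 0.25, 0.50, 0.75, 0.90),
        tag: str = "hp",
    ) -> "QuantileSurface":
        """Summarize an (n_members, n_rows, n_cols) prediction array.

        The five quantile grids are cellwise empirical quantiles over the
        members; mean and sd (ddof=1) come from the five-grid stack, and the
        90% interval is mean +/- 1.645 sd clipped at zero.
        """
        stack = np.quantile(member_preds, list(quantiles), axis=0)
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        lo = np.clip(mean - _Z90 * sd, 0.0, None)
        hi = mean + _Z90 * sd
        grids = {}
        for q, layer in zip(quantiles, stack):
            name = f"q{int(round(q * 100))}"
            grids[name] = template.with_values(
                np.where(template.mask, 0.0, layer), tag=f"{tag}_{name}"
            )
        mk = lambda arr, name: template.with_values(
            np.where(template.mask, 0.0, arr), tag=f"{tag}_{name}"
        )
        return cls(grids["q10"], grids["q25"], grids["q50"], grids["q75"], grids["q90"],
                   mk(mean, "mean"), mk(sd, "sd"), mk(lo, "ci_lo"), mk(hi, "ci_hi"))

    def grids(self) -> dict[str, Grid]:
        return {"q10": self.q10, "q25": self.q25, "q50": self.q50, "q75": self.q75,
                "q90": self.q90, "mean": self.mean, "sd": self.sd,
                "ci_lo": self.ci_lo, "ci_hi": self.ci_hi}


@dataclass
class HHREnsemble:
    """Fitted harvest-rate ensemble plus the full-data importance ranking."""

    members: list[RandomForestRegressor]
    full_model: RandomForestRegressor
    feature_names: list[str]
    importances: pd.Series
    reference_span: float
    spec: EnsembleSpec


def _design_matrix(features: pd.DataFrame, feature_names: Sequence[str]) -> np.ndarray:
    missing = [c for c in feature_names if c not in features.columns]
    if missing:
        raise AlignmentError(f"feature table lacks covariates {missing}")
    return features[list(feature_names)].to_numpy(dtype=float)


def fit_hhr_ensemble(
    features: pd.DataFrame,
    hhr: pd.Series | np.ndarray,
    spec: EnsembleSpec | None = None,
    span_col: str = SPAN_COVARIATE,
    min_rows: int = 20,
    n_importance_repeats: int = 5,
) -> HHREnsemble:
    """Fit the subsampled forest ensemble for the overall harvest rate.

    ``features`` must contain the recording-span effort covariate; every
    other non-identifier column is used as a predictor (categorical layers
    arrive as integer level codes, which tree splits handle natively). The
    permutation-importance ranking is computed once on a forest fitted to
    100% of the rows.
    """
    spec = spec or EnsembleSpec()
    y = np.asarray(hhr, dtype=float)
    feature_names = [c for c in features.columns if c not in ("locality_id", "year")]
    if span_col not in feature_names:
        raise AlignmentError(f"features must include the {span_col!r} effort covariate")
    X = _design_matrix(features, feature_names)
    if len(X) < min_rows:
        raise ValueError(f"need at least {min_rows} training rows, got {len(X)}")
    if np.ptp(y) == 0:
        warnings.warn("constant response: ensemble will predict a constant", stacklevel=2)

    n_sub = max(1, int(round(spec.subsample_fraction * len(X))))
    members = []
    for m in range(spec.n_members):
        member_seed = spec.seed + 1 + m
        idx = np.random.default_rng(member_seed).choice(len(X), size=n_sub, replace=False)
        model = RandomForestRegressor(
            n_estimators=spec.n_trees, random_state=member_seed, n_jobs=1
        )
        model.fit(X[idx], y[idx])
        members.append(model)

    full = RandomForestRegressor(n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1)
    full.fit(X, y)
    imp = permutation_importance(
        full, X, y, n_repeats=n_importance_repeats, random_state=spec.seed, n_jobs=1
    )
    importances = pd.Series(imp.importances_mean, index=feature_names).sort_values(
        ascending=False
    )
    return HHREnsemble(
        members=members,
        full_model=full,
        feature_names=feature_names,
        importances=importances,
        reference_span=float(np.median(features[span_col])),
        spec=spec,
    )


def stack_feature_matrix(
    stack: GridStack,
    feature_names: Sequence[str],
    prediction_year: int | None = None,
    constants: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, Grid]:
    """Per-cell design matrix over the stack's unmasked cells.

    Time-varying layers are resolved at ``prediction_year`` (default: the
    latest epoch) via nearest-epoch matching; ``constants`` supplies values
    for non-spatial covariates (e.g. the recording span fixed at a reference
    effort). Returns (X, flat cell indices, a template grid).
    """
    constants = dict(constants or {})
    template = stack.all_grids()[0]
    valid = ~template.mask
    for g in stack.all_grids():
        valid &= ~g.mask
    flat = np.flatnonzero(valid.ravel())
    cols = []
    table = stack.epoch_table()
    for name in feature_names:
        if name in constants:
            cols.append(np.full(flat.size, float(constants[name])))
        elif name in stack.temporal:
            year = prediction_year
            if year is None:
                year = max(stack.temporal[name])
            epoch = match_epoch(int(year), name, table)
            cols.append(stack.temporal[name][epoch].values.ravel()[flat])
        elif name in stack.static:
            cols.append(stack.static[name].values.ravel()[flat])
        else:
            raise AlignmentError(f"prediction stack lacks layer {name!r}")
    X = np.column_stack(cols) if cols else np.empty((flat.size, 0))
    tmpl = Grid(np.zeros(template.shape), ~valid, template.cell_area, "template")
    return X, flat, tmpl


def predict_hp(
    ensemble: HHREnsemble,
    stack: GridStack,
    prediction_year: int | None = None,
    span_value: float | None = None,
    tag: str = "hp",
) -> QuantileSurface:
    """Predict the harvest-productivity quantile surface over a stack.

    The recording-span effort covariate is fixed at a reference value (the
    training-set median by default): predictions are potential rates at a
    standard monitoring effort, not at any study's particular effort.
    """
    span = ensemble.reference_span if span_value is None else float(span_value)
    X, flat, template = stack_feature_matrix(
        stack, ensemble.feature_names, prediction_year, {SPAN_COVARIATE: span}
    )
    preds = np.stack([m.predict(X) for m in ensemble.members])
    preds = np.clip(preds, 0.0, None)
    cube = np.zeros((len(ensemble.members),) + template.shape)
    for k in range(len(ensemble.members)):
        cube[k].ravel()[flat] = preds[k]
    return QuantileSurface.from_member_predictions(
        cube, template, ensemble.spec.quantiles, tag=tag
    )


# ---------------------------------------------------------------------------
# TSOP training and prediction
# ---------------------------------------------------------------------------

def _ancestors(taxon: str, registry: pd.DataFrame) -> set[str]:
    parents = dict(zip(registry["taxon_id"], registry.get("parent_id", pd.Series(dtype=object))))
    out: set[str] = set()
    cur = parents.get(taxon)
    while cur is not None and not (isinstance(cur, float) and np.isnan(cur)) and cur != "":
        if cur in out:
            break
        out.add(cur)
        cur = parents.get(cur)
    return out


def build_tsop_training(
    tsop: pd.DataFrame,
    localities: pd.DataFrame,
    taxon: str,
    range_mask: np.ndarray,
    registry: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Training rows (locality_id, tsop) for one taxon's composition model.

    Positive rows are localities where the taxon was harvested. Localities
    inside the taxon's range where other taxa were harvested but this one was
    not contribute explicit zeros (true absences, not missing data).
    Localities recording both the taxon and one of its enclosing higher taxa
    are excluded — part of the harvest hides inside the higher label, so the
    observed proportion would understate the truth. Out-of-range localities
    with no harvest of the taxon contribute nothing.
    """
    range_mask = np.asarray(range_mask, dtype=bool)
    loc = localities.set_index("locality_id")
    observed = tsop[taxon] if taxon in tsop.columns else pd.Series(0.0, index=tsop.index)

    excluded: set[str] = set()
    if registry is not None and "parent_id" in registry.columns:
        ancestors = _ancestors(taxon, registry)
        for anc in ancestors:
            if anc in tsop.columns:
                both = tsop.index[(tsop[anc] > 0) & (observed > 0)]
                excluded.update(both)

    rows = []
    for lid in tsop.index:
        if lid in excluded or lid not in loc.index:
            continue
        value = float(observed.loc[lid])
        if value > 0:
            rows.append({"locality_id": lid, "tsop": value})
        else:
            r, c = int(loc.loc[lid, "row"]), int(loc.loc[lid, "col"])
            if range_mask[r, c]:
                rows.append({"locality_id": lid, "tsop": 0.0})
    return pd.DataFrame(rows, columns=["locality_id", "tsop"])


def fit_predict_tsop(
    training: pd.DataFrame,
    features: pd.DataFrame,
    stack: GridStack,
    spec: EnsembleSpec | None = None,
    prediction_year: int | None = None,
    min_rows: int = 10,
    tag: str = "tsop",
) -> tuple[Grid, bool]:
    """Fit one taxon's composition forest and predict its raw surface.

    Uses the same covariates as the harvest-rate model except the
    recording-span effort control. Taxa with fewer than ``min_rows`` training
    localities are flagged unmodelled and fall back to a constant surface at
    the training mean (0 when there is no training at all). Predictions are
    clipped to [0, 1]. Returns ``(surface, modelled)``.
    """
    spec = spec or EnsembleSpec()
    feature_names = [
        c for c in features.columns
        if c not in ("locality_id", "year", SPAN_COVARIATE)
    ]
    merged = training.merge(features, on="locality_id", how="left")
    y = merged["tsop"].to_numpy(dtype=float)
    X_cols, flat, template = stack_feature_matrix(stack, feature_names, prediction_year)
    if len(training) < min_rows:
        const = float(y.mean()) if len(y) else 0.0
        values = np.zeros(template.shape)
        values.ravel()[flat] = const
        return template.with_values(np.clip(values, 0.0, 1.0), tag=tag), False
    X = _design_matrix(merged, feature_names)
    model = RandomForestRegressor(n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1)
    model.fit(X, y)
    pred = np.clip(model.predict(X_cols), 0.0, 1.0)
    values = np.zeros(template.shape)
    values.ravel()[flat] = pred
    return template.with_values(values, tag=tag), True


@dataclass
class TSOPStack:
    """Range-clipped, cellwise-renormalized composition stack.

    ``proportions`` maps taxon id to its proportion grid; ``valid`` marks
    cells where at least one in-range taxon had positive raw weight (the
    proportions there sum to 1). The unidentified-harvest bucket never gets
    a surface of its own: its share is redistributed by the renormalization.
    """

    proportions: dict[str, Grid]
    valid: np.ndarray

    def sum_surface(self) -> np.ndarray:
        return np.sum([g.values for g in self.proportions.values()], axis=0)


def assemble_tsop_stack(
    raw_surfaces: Mapping[str, Grid],
    range_masks: Mapping[str, np.ndarray],
) -> TSOPStack:
    """Clip each raw proportion surface to its range and renormalize cellwise.

    Out-of-range cells are zeroed; on cells with positive clipped sum every
    surface is divided by that sum so the stack sums to exactly 1; cells with
    zero sum are flagged invalid (masked).
    """
    if not raw_surfaces:
        raise ValueError("need at least one raw surface")
    tags = list(raw_surfaces)
    template = raw_surfaces[tags[0]]
    clipped = {}
    for t in tags:
        g = raw_surfaces[t]
        if g.shape != template.shape:
            raise AlignmentError("raw TSOP surfaces are not aligned")
        mask = np.asarray(range_masks.get(t, np.ones(g.shape, dtype=bool)), dtype=bool)
        clipped[t] = np.where(mask & ~g.mask, np.clip(g.values, 0.0, 1.0), 0.0)
    total = np.sum(list(clipped.values()), axis=0)
    valid = (total > 0) & ~template.mask
    proportions = {}
    for t in tags:
        vals = np.zeros(template.shape)
        vals[valid] = clipped[t][valid] / total[valid]
        proportions[t] = Grid(vals, ~valid, template.cell_area, f"tsop_{t}")
    return TSOPStack(proportions=proportions, valid=valid)
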