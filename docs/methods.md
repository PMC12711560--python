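# Methods

## Scope and assumptions

The package estimates wildlife harvest over a pre-aligned rectangular
lattice of 10 × 10 km cells (100 km² each). All layers — covariates,
population, predictions — must share that lattice; reprojection and
resampling of real-world rasters are upstream concerns, as the science here
is lattice-level. Values are carried as 2D float arrays with an explicit
nodata mask; file round-trips use single-band float32 TIFF with the layer
tag, cell area and any categorical level registry in a JSON description
tag.

The harvest model assumes: (1) locality-level counts are Poisson given the
cell's latent harvest rate and the monitored hunter-days; (2) the taxon
split of a locality's harvest is multinomial over the taxa whose geographic
range covers the cell; (3) hunters are a roughly constant fraction of rural
consumers (median 0.178); and (4) the latent rate is a smooth function of
environmental and anthropogenic covariates. None of these assumptions is
imposed on the data — they are what the synthetic generator emulates and
what the estimators are designed to recover.

## Record filters and metrics

Localities reporting fewer than four distinct determined taxa are excluded
from all analyses (such studies carry little compositional information);
the reserved `undetermined` label does not count toward the threshold, a
choice made because that bucket aggregates arbitrarily many species.
Localities without a usable effort row (positive hunters and span) are
additionally excluded from the harvest-rate set only. `compute_hhr` assigns
a genuine zero rate to every locality present in its effort table, so
effort rows must first be subset to the filtered study set
(`efforts_for`); passing the unfiltered effort table would re-admit
filtered-out localities as spurious zero-rate observations.

The hunter-to-consumer ratio is summarized as the median and
10/25/75/90% quantiles of per-locality ratios; when no locality data are
supplied the published constants (0.178; 0.168, 0.173, 0.183, 0.187) are
used, with the sd backed out of the quantile spread as
(q90 − q10)/(2 z₀.₉₀) ≈ 0.0074.

## Monte Carlo propagation

Scalar traits are propagated by drawing 1,000 values from N(mean, se),
where se = sd/√n over the trait observations (se = 0 for a single
observation). For strictly positive quantities negative draws are rejected
and redrawn rather than truncated, avoiding a spurious probability atom at
zero in the reported quantiles. A `MetricEstimate` stores the mean, sd and
10/25/50/75/90% quantiles of the draws. Two interval conventions coexist:
the (q10, q90) pair of the draws is the reported quantile interval (80%
central mass for a normal), while `ci90` is the normal-theory interval
mean ± 1.645 sd, which is the interval with true 90% coverage; calibration
checks use the latter.

## Ensemble and surfaces

The harvest-rate model is an ensemble of 30 scikit-learn regression
forests (500 trees each by default), member *m* trained on a seeded 70%
subsample without replacement (member seed = base seed + 1 + m).
Categorical covariates enter as integer level codes — tree splits handle
them natively. Cellwise empirical quantiles {10, 25, 50, 75, 90}% across
the member predictions define the quantile surface; the mean and sd (ddof
1) come from that five-grid stack and the 90% interval is mean ± 1.645 sd
clipped at zero. A single forest fitted to 100% of the rows provides the
permutation-importance ranking. At prediction time the recording-span
effort covariate is fixed at the training-set median: it is a nuisance
control, and predictions represent potential rates at a reference
monitoring effort.

Composition (TSOP) models are single seeded forests per taxon on the same
covariates minus the effort term, fitted to the raw proportions without a
logit transform. Training rows are the localities harvesting the taxon,
plus explicit zeros at in-range localities that harvested other taxa but
not this one (true absences); localities recording both a taxon and one of
its enclosing higher taxa are excluded from the lower taxon's training set,
since part of its harvest hides inside the higher label. Taxa with fewer
than 10 training localities are flagged unmodelled and fall back to a
constant surface at the training mean. Raw surfaces are clipped to [0, 1]
and to the taxon's range, then renormalized cellwise so in-range
proportions sum to exactly 1; cells with zero clipped sum are masked. The
unidentified-harvest bucket enters locality denominators but never gets a
surface; renormalization redistributes its share.

Time-varying covariates (habitat loss from 1985, greenness/productivity
from 2000, both at 5-year snapshots) are matched to record years by nearest
epoch with clamping at both ends — pre-1988 records use the 1985
habitat-loss snapshot, post-2018 records the 2020 one. Gap filling replaces
each missing cell by the mean of its available 8-neighbours, iterated
Jacobi-style to convergence (max 50 passes); observed cells are never
altered and fills obey the discrete maximum principle.

## Offtake accounting

Annual per-taxon extraction per cell is HP × hunters × 365 (leap years
ignored). For taxa with density data the per-cell annual take is truncated
at the mean standing density of one cell (individuals per 100 km² times
cell area/100); the cap is the standing stock itself, with no
harvest-fraction multiplier, because density is the only abundance
information available. Biomass multiplies individuals by body-mass
quantiles; the edible fraction defaults to the pooled 0.585 of undressed
biomass, with a per-group alternative (mammals 0.63, birds 0.73, chelonians
0.47, caimans 0.45). Uncertainty propagates quantile-by-quantile — the q10
rate surface is combined with the q10 hunter ratio and q10 masses — never
mixing quantile levels; this brackets rather than integrates the joint
distribution, a deliberate simplification matching the stack-then-summarize
design. Per-capita availability masks (rather than zeroes) cells with no
rural population. The beef counterfactual converts annual edible production
to pasture area at a configurable yield (kg/ha/day) and to CO₂ at
18,000 t/km²; it exposes the formula, not any particular published
interval. Monetary valuation is reported only when a beef price is
supplied.

## Nutrition

Requirement surfaces multiply the rural-population grid by demographic
shares (children/women/men) and per-person dietary reference values — EAR
preferred, AI/RDA fallback, AMDR midpoint for total fat, EER for energy —
and sum over groups, so requirements are exactly proportional to
population. The packaged DRI table uses standard reference values and is an
editable CSV, as are the demographic shares; the packaged composition
observations are synthetic defaults (labelled as such in the filename) with
a mandatory unit column — no units are assumed. Taxa lacking composition
data inherit their group mean, then the pooled mean (food matching).
Adequacy per cell is 100 × supplied/required, masked where the requirement
is zero; the summary per nutrient is the requirement-weighted aggregate,
which equals total supplied over total required. Published continental
adequacy percentages are shipped as reference metadata only
(`published_adequacy_reference.csv`): they depend on composition and DRI
tables not distributed here, so nothing asserts them.

## Synthetic generator

Continuous covariate fields are Gaussian-smoothed white noise
(σ = 3 cells), standardized; categorical layers (language family, urban–
rural catchment class, Indigenous-land indicator) are argmax over smoothed
fields, giving contiguous patches. The study boundary is an ellipse
covering most of the lattice; urban cells are the highest-population
fraction of inside cells. The true harvest rate is a known monotone
function of greenness (the designated driver) minus habitat-loss and
flooding terms plus small language-family offsets, clipped at zero —
roughly 0.02–0.13 individuals per hunter-day, centred near 0.07. The truth
is defined on the latest-epoch covariates, the state any prediction surface
is evaluated against; records observe epoch-matched (hence slightly noisy)
covariate values. Body masses are log-normal (ln-sd 2.3, so a ~500-taxon
pool spans about six orders of magnitude); densities are log-normal around
200 individuals/100 km² and assigned to 80% of taxa. Ranges are contiguous
disks covering ≥ 10% of inside cells; the first taxon is a full-range
generalist so every cell has at least one in-range taxon. Communities have
Poisson consumer counts (mean 120, floor 10) and binomial hunters; each
locality's records derive from an independent RNG substream keyed on (seed,
locality index), so optional features never perturb other localities'
draws. Recording spans are uniform over a configurable interval (default
60–400 days) to exercise the effort covariate.

What passing recovery tests show — and do not show: the estimators recover
a smooth, static, covariate-driven rate from Poisson counts under the
generator's assumptions. Real hunting data add temporal drift in the rate
itself, non-random hunter selection, reporting error and spatial
aggregation of localities, none of which the generator emulates; recovery
here validates the machinery, not the field accuracy of any particular
continental estimate.

## Numerical and design choices

- Stage seeds derive from the root seed via SHA-256 of "seed:stage",
  truncated below 2³¹; two runs with one config are byte-identical.
- Quantiles use numpy's default linear interpolation; ties in epoch
  matching cannot arise (integer years against 5-year grids).
- The pipeline's default problem size (40 × 40 cells, 12 taxa, 120
  localities) mirrors the validation fixtures; the recovery experiment uses
  600 localities, where label noise is far below the spatial signal.
- The CLI is deliberately thin: `simulate` and `run --stop-after <stage>`
  wrap the library pipeline; all stage logic lives in importable functions.

## Known limitations

Single-fit TSOP models carry no between-model uncertainty (the ensemble
machinery is reusable if that is wanted). Quantile-matched propagation
ignores dependence structure across sources of uncertainty. The density cap
is a standing-stock bound, not a sustainability criterion — this package
deliberately makes no sustainability claims. Nutrient adequacy ignores
bioavailability and dietary substitution.
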