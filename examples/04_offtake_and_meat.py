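"""From harvest rates to annual offtake, edible meat and the beef comparison.

Annual extraction per cell is rate x hunters x 365, split across taxa by the
composition stack and capped at each taxon's standing density; biomass
follows by body mass, edible meat by the 0.585 carcass yield, and per-capita
availability by the rural population grid.
"""

import numpy as np

from wildmeat import synthetic as syn
from wildmeat.grids import Grid, derive_apps, derive_rhps
from wildmeat.models import assemble_tsop_stack
from wildmeat.offtake import (
    beef_counterfactual,
    biomass_surfaces,
    density_cap_per_cell,
    edible_production,
    individuals_offtake,
    per_capita_availability,
    taxon_individual_hp,
)
from wildmeat.records import hunter_consumer_ratio

land = syn.generate_landscape(syn.LandscapeConfig(n_rows=30, n_cols=30, seed=7))
taxa, ranges, _ = syn.generate_taxa(10, land.shape, land.boundary_mask, seed=8)
rng = np.random.default_rng(9)

# composition stack (here: noisy raw surfaces, clipped to range, renormalized)
raw = {t.taxon_id: Grid(np.abs(rng.normal(0.2, 0.1, land.shape)), tag=t.taxon_id)
       for t in taxa}
tsop = assemble_tsop_stack(raw, ranges)
hp = Grid(land.true_hp, ~land.boundary_mask, tag="hp")

apps = derive_apps(land.population, land.urban_mask, land.boundary_mask)
ratio = hunter_consumer_ratio(None)  # published constants
rhps = derive_rhps(apps, {"q50": ratio.q50})["q50"]
print(f"rural population {apps.total():,.0f}; hunters {rhps.total():,.0f} "
      f"({ratio.q50:.3f} of consumers)")

taxon_hp = taxon_individual_hp(hp, tsop.proportions)
caps = {t.taxon_id: density_cap_per_cell(t) for t in taxa if t.density is not None}
offtake = individuals_offtake(taxon_hp, rhps, caps)
total_ind = sum(o.individuals.total() for o in offtake.values())
n_trunc = sum(o.truncated.sum() for o in offtake.values())
print(f"annual offtake: {total_ind:,.0f} individuals; density cap binds on "
      f"{n_trunc} taxon-cells")

masses = {t.taxon_id: t.body_mass for t in taxa}
individuals = {t: o.individuals for t, o in offtake.items()}
_, overall = biomass_surfaces(individuals, masses, quantiles=("q50",))
edible = edible_production(overall["q50"])
print(f"biomass {overall['q50'].total():,.0f} kg/yr -> edible "
      f"{edible.total():,.0f} kg/yr (58.5% of undressed)")

daily = edible.with_values(edible.values / 365.0)
per_capita = per_capita_availability(daily, apps)
ok = ~per_capita.mask
weighted = (per_capita.values[ok] * apps.values[ok]).sum() / apps.values[ok].sum()
print(f"edible meat per rural inhabitant: {weighted:.1f} g/day "
      f"(population-weighted mean)")

area, co2 = beef_counterfactual(edible.total(), yield_kg_per_ha_day=0.5)
print(f"replacing this with beef at 0.5 kg/ha/day would need {area:,.1f} km2 "
      f"of pasture, releasing {co2:.3f} Mt CO2 at 18,000 t/km2")
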