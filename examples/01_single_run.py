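"""One default simulation: five diel wet-dry cycles of surface colonization.

A population founded by 100 planktonic cells colonizes a 1 mm^2 surface
under a 12 h wet / 12 h dry cycle, using the preferential-attachment
strategy (threshold Q_PA = 12).  Prints the final population yield, its
planktonic/sessile split, and the aggregate structure of the biofilm.
"""

import numpy as np

from surfcol import SimulationParams, run, population_yield, snapshot_aggregates

params = SimulationParams()
result = run(params, seed=1)

snap = result.final_snapshot
aggs = snapshot_aggregates(snap, params)
sizes = np.array([a.size for a in aggs])
protected = sizes[sizes >= params.Q_L]

print(f"population yield after {params.n_days} days: {population_yield(result)}")
print(f"  planktonic: {(snap.state == 'planktonic').sum()}, "
      f"sessile: {(snap.state == 'sessile').sum()}")
print(f"  aggregates: {len(aggs)}, of which {len(protected)} are "
      f"stress-protected (size >= Q_L = {params.Q_L})")
print(f"  cells in protected aggregates: {protected.sum()} "
      f"({protected.sum() / max(1, sizes.sum()):.0%} of the biofilm)")
print(f"  nutrient at the end of the run: {result.timeseries.c.iloc[-1]:.2f} g/m^3")
# The yield is the study's fitness measure: the cells alive after the
# last dry period.  A high protected fraction means the colonization
# strategy converted growth into desiccation-proof aggregates.
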