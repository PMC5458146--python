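"""Palaeogeographic-spread metrics on a 1-degree grid.

Bins a cloud of localities into grid cells, builds the minimum spanning tree
over cell centroids and prints the five spread metrics, then shows how the
metrics co-vary across many random pools.
"""

import numpy as np

from paleospread import SpatialPool, bin_to_grid, metric_correlations

rng = np.random.default_rng(7)

# one pool: 60 localities clustered around three centres
centres = [(35, -5), (42, 10), (30, 20)]
colls = {}
for i in range(60):
    clat, clon = centres[i % 3]
    colls[f"c{i}"] = (clat + rng.normal(0, 2.5), clon + rng.normal(0, 2.5))

pool = SpatialPool.from_cells("demo", "B1", bin_to_grid(colls))
m = pool.metrics
print(f"occupied 1-degree cells : {m.n_grid_cells}")
print(f"summed MST length       : {m.summed_mst_km:,.0f} km")
print(f"max great-circle dist   : {m.max_gcd_km:,.0f} km")
print(f"standard distance       : {m.standard_distance_km:,.0f} km")
print(f"convex-hull area        : {m.convex_hull_km2:,.0f} km^2")
# summed MST length is the spread currency used for standardization: the
# shortest total road network connecting every occupied cell.

# correlations across 40 random pools of varying extent
pools = []
for p in range(40):
    n = int(rng.integers(5, 40))
    lat0, lon0 = rng.uniform(-30, 50), rng.uniform(-60, 60)
    scale = rng.uniform(1, 8)
    c = {f"c{i}": (lat0 + rng.normal(0, scale), lon0 + rng.normal(0, scale))
         for i in range(n)}
    pools.append(SpatialPool.from_cells(f"p{p}", "B1", bin_to_grid(c)))
print("\nPearson correlations of spread metrics across pools:")
print(metric_correlations(pools).round(2).to_string())
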