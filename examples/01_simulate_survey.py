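"""Generate a synthetic cluster-sampled survey world and describe it.

Builds a 100 x 100 km region with smooth covariate rasters, a latent
Matérn fertility field, 250 stratified survey clusters with design
weights, and retrospective birth histories for each sampled woman.
"""

import numpy as np

from fertimap.seeding import substream_seed
from fertimap.synthetic import (
    SimulationConfig,
    simulate_birth_histories,
    simulate_clusters,
    simulate_covariate_rasters,
    simulate_matern_field,
)

cfg = SimulationConfig(seed=1)
stack = simulate_covariate_rasters(cfg)
field = simulate_matern_field(cfg.grid, cfg.matern, substream_seed(cfg.seed, "field"))
clusters = simulate_clusters(cfg)
women = simulate_birth_histories(clusters, stack, field, cfg)

n_urban = sum(c.urban for c in clusters)
births = sum(len(w.child_dobs_cmc) for w in women)
print(f"covariate layers : {', '.join(stack.names)}")
print(f"grid             : {cfg.grid.n_rows} x {cfg.grid.n_cols} pixels at "
      f"{cfg.cell_km} km")
print(f"clusters         : {len(clusters)} ({n_urban} urban), "
      f"mean design weight {np.mean([c.weight for c in clusters]):.3f}")
print(f"women            : {len(women)}, births in 3-year window: {births}")
print(f"latent field sd  : {field.values.std():.3f} "
      f"(target sqrt(sigma2) = {np.sqrt(cfg.matern.sigma2):.3f})")
# The birth count divided by total woman-years (~3 per woman) approximates
# the summed age-specific fertility rate, i.e. roughly TFR/5 per woman-year.
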