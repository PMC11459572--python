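"""Bayesian kriging of cluster-level proportions onto the map grid.

Cluster-level proportions of Muslim women (binomial observations of a
smooth latent surface) are interpolated with a Matérn Gaussian process,
integrating over an 11 x 11 x 5 grid of (sill, range, nugget) nodes.
"""

import numpy as np

from fertimap.kriging import krige_fit, krige_predict
from fertimap.synthetic import (
    SimulationConfig,
    simulate_cluster_proportions,
    simulate_clusters,
    simulate_covariate_rasters,
)

cfg = SimulationConfig(seed=1)
stack = simulate_covariate_rasters(cfg)
clusters = simulate_clusters(cfg)
props = simulate_cluster_proportions(clusters, stack, cfg)

fit = krige_fit(props[["x_km", "y_km"]].to_numpy(),
                props["proportion"].to_numpy(),
                sample_weights=props["n_women"].to_numpy())
mean, sd = krige_predict(fit, cfg.grid)

best = fit.nodes[int(np.argmax(fit.weights))]
truth = stack["prop_muslim"].values
rmse = float(np.sqrt(np.mean((mean.values - truth) ** 2)))
print(f"observed cluster proportions: {props['proportion'].min():.2f} "
      f"to {props['proportion'].max():.2f} (n = {len(props)})")
print(f"posterior-modal hypers: sill {best.sigma2:.4f}, "
      f"range {best.range_km:.1f} km, nugget {best.nugget:.4f}")
print(f"kriged surface range: {mean.values.min():.2f} to {mean.values.max():.2f}")
print(f"RMSE against the true latent surface: {rmse:.3f}")
print(f"mean posterior sd: {sd.values.mean():.3f}")
# The nugget absorbs the binomial sampling noise of ~25 women per cluster,
# so the kriged mean is smoother than the raw cluster proportions.
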