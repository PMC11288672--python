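"""Recovering anisotropy with temperature-parallel simulated annealing.

The toy target is nonlinear in coordinate 1 and linear in coordinate 2, so
a good locality matrix must localize coordinate 1 much harder.  The
annealer starts from the isotropic identity and finds that structure.
"""

import numpy as np

from lmdr.simulators import anisotropic_toy_embedding
from lmdr.tpsa import TPSAConfig, find_best_theta

X = anisotropic_toy_embedding(m=100, seed=0)
res = find_best_theta(
    X,
    config=TPSAConfig(n_chains=4, sigma_delta=0.3, sigma_lambda=0.005,
                      n_mutations_per_round=30, n_exchange_rounds=25, master_seed=0),
)

d = np.diag(res.best_theta.theta)
print("target: y = sin(2.5 x1) + 0.3 x2 + noise")
print(f"optimized locality diagonal: theta_11 = {d[0]:.2f}, theta_22 = {d[1]:.2f}")
print(f"ridge penalty lambda = {res.best_lambda:.5f}")
print(f"leave-one-out RMSE: {res.meta['initial_energy']:.4f} (isotropic start) "
      f"-> {res.skill.rmse:.4f} (optimized)")
print("theta_11 >> theta_22: the annealer localizes the nonlinear coordinate "
      "and leaves the linear one nearly global.")
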