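"""Predator-prey pipeline on a synthetic microcosm-style count series.

Runs the full empirical protocol — standardization, simplex-projection
embedding-dimension selection, LMDr and MDR S-map fits, and a short
sampling-error replicate sweep — on the package's Holling type II
predator-prey fixture, then reports interaction signs and forecast skill.
"""

import numpy as np

from lmdr import SamplingErrorModel, make_protozoa_fixture, run_protozoa_analysis
from lmdr.tpsa import TPSAConfig

exp = make_protozoa_fixture(m=70, seed=1)
print(f"fixture: {len(exp.series)} samples every 12 h, "
      f"prey ~{exp.series.column('Pa').mean():.0f}, "
      f"predator ~{exp.series.column('Dn').mean():.0f} counts")

results = run_protozoa_analysis(
    [exp],
    methods=("LMDr", "mdr_smap"),
    error_model=SamplingErrorModel(n_replicates=10, seed=1),
    seed=1,
    tpsa=TPSAConfig(n_chains=3, sigma_delta=0.5, sigma_lambda=0.01,
                    n_mutations_per_round=15, n_exchange_rounds=12),
)

r = results[exp.name]
for t in r["clean"]:
    direction = "dPa(t+1)/dDn(t)" if t.target == "Pa" else "dDn(t+1)/dPa(t)"
    frac = (t.cross_jacobian < 0).mean() if t.target == "Pa" else (t.cross_jacobian > 0).mean()
    expected = "negative (predation)" if t.target == "Pa" else "positive (feeding)"
    print(f"{t.method:9s} {direction}: E = {t.embedding_dim}, "
          f"LOO rho = {t.skill.pearson_rho:.3f}, "
          f"expected-sign fraction = {frac:.2f} ({expected})")

clean_pa = next(t for t in r["clean"] if t.method == "LMDr" and t.target == "Pa")
dens = clean_pa.densities["Pa"].to_numpy()
lo, hi = np.quantile(dens, [1 / 3, 2 / 3])
at_low = clean_pa.cross_jacobian[dens <= lo].mean()
at_high = clean_pa.cross_jacobian[dens >= hi].mean()
print(f"\nper-predator effect on prey, dPa/dDn: {at_low:+.3f} at low prey density "
      f"vs {at_high:+.3f} at high prey density")
print("the estimated effect is density-dependent, not a constant: this "
      "Jacobian-vs-density relationship is what the functional-response "
      "summary (quadratic fits with replicate bands) characterizes.")
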