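"""Simulate a two-community case-control cohort and refit it.

Draws 200 samples from a mixture of two latent communities -- a low-risk
one (disease probability 0.2) and a high-risk one (0.8) -- then recovers
the mixing weights, risks and compositions by annealed EM.
"""

import numpy as np

from bermix import SimulationConfig, fit, generate

config = SimulationConfig(
    N=200, K=12, L=2, M=2000,
    phi=[0.6, 0.4],          # 60% of samples in the low-risk community
    rho=[0.2, 0.8],          # per-community disease risk
    alpha=1.0,               # flat Dirichlet for the composition rows
    seed=42,
)
sim = generate(config)
print(f"simulated {sim.data.n_samples} samples x {sim.data.n_taxa} taxa, "
      f"{sim.data.labels.sum()} cases")

result = fit(sim.data, L=2, gamma=1e-9, seed=0)
p = result.params
print(f"estimated mixing weights phi: {np.round(p.phi, 3)}   (truth: 0.6, 0.4)")
print(f"estimated disease risks rho:  {np.round(p.rho, 3)}   (truth: 0.2, 0.8)")
err = np.abs(p.P - sim.true_params.P).max()
print(f"max abs error in composition rows: {err:.4f}")
print("clusters are reported risk-ascending: cluster 1 is the low-risk community;")
print("a small composition error means the fit recovered what generated the data.")
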