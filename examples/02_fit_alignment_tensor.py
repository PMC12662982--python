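"""Fit a single alignment tensor to simulated RDC + ΔΔRCSA data.

Generates a 3-conformer toy ensemble, simulates noisy anisotropic data from
a known tensor, fits it back and compares with the truth.
"""

import numpy as np

import anisofit as af

ensemble = af.make_toy_ensemble(3, seed=1)
populations = af.PopulationSet.uniform(ensemble.conformer_ids)
true_tensor = af.make_true_tensor(5.0e-4, rhombicity=0.3, orientation_seed=7)

truth = af.SyntheticTruth(
    true_tensor, populations,
    noise=af.NoiseModel(sigma_rdc_hz=0.5, sigma_rcsa_ppb=2.0), seed=11)
data = af.simulate_dataset(ensemble, truth)
print(f"simulated {len(data.rdcs)} one-bond C-H RDCs and "
      f"{len(data.rcsas)} carbon RCSAs")

result = af.fit_data(
    ensemble, populations,
    list(data.rdcs) + list(data.rcsas),
    af.shielding_map(data.shieldings),
    mc_draws=500, seed=1,
)
vals, _ = result.tensor.principal()
tvals, _ = true_tensor.principal()
print(f"fitted principal values  Sxx, Syy, Szz = "
      f"{vals[0]:+.3e} {vals[1]:+.3e} {vals[2]:+.3e}")
print(f"true   principal values  Sxx, Syy, Szz = "
      f"{tvals[0]:+.3e} {tvals[1]:+.3e} {tvals[2]:+.3e}")
print(f"Q(rdc) = {result.q_rdc:.4f}   Q(rcsa) = {result.q_rcsa:.4f}   "
      f"Q(combined) = {result.q_combined:.4f} ± {result.q_combined_se:.4f} (MC)")
print(f"condition number of the design matrix = {result.condition_number:.1f}")
print()
print("A Q factor this small means the data are fully explained by one")
print("shared tensor over the population-weighted ensemble; Q near or")
print("above ~0.3 would instead signal a wrong structure or ensemble.")
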