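"""Akaike selection of conformer populations from chemical shifts.

A 0.7/0.3 two-conformer mixture hidden in a 6-conformer pool is recovered
purely from ¹H/¹³C shifts — no energies involved — and the selected
ensemble is then fitted against anisotropic data.
"""

import anisofit as af

pool = af.make_toy_ensemble(6, seed=5)
true_pops = af.PopulationSet(
    {"c1": 0.0, "c2": 0.7, "c3": 0.0, "c4": 0.0, "c5": 0.3, "c6": 0.0})
truth = af.SyntheticTruth(
    af.make_true_tensor(5.0e-4, 0.3, orientation_seed=5), true_pops,
    af.NoiseModel(sigma_c13_ppm=0.2, sigma_h1_ppm=0.02), seed=5)
data = af.simulate_dataset(pool, truth)

models = af.enumerate_models(pool, data.shifts, max_subset_size=3,
                             nucleus="c13")
print("top 3 conformer ensembles by AICc (13C shifts):")
for m in models[:3]:
    pops = {c: round(p, 3) for c, p in m.populations.items()}
    print(f"  S{m.rank}: subset {list(m.subset)}  AICc {m.aic:8.2f}  "
          f"populations {pops}")

best = models[0]
selected = pool.subset(best.subset)
fitted_pops = af.PopulationSet.fitted(best.populations)
result = af.fit_data(
    selected, fitted_pops, list(data.rdcs) + list(data.rcsas),
    af.shielding_map(data.shieldings))
print(f"\nanisotropic fit of the selected ensemble: "
      f"Q(combined) = {result.q_combined:.3f}")
print()
print("The AICc-best ensemble is the generating pair with populations close")
print("to the 0.70/0.30 truth; feeding it into the alignment-tensor fit")
print("closes the loop between shift-based selection and anisotropic data.")
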