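"""Rank two candidate relative configurations by fit to anisotropic data.

Simulates experimental RDC/ΔΔRCSA data from a "true" configuration, builds
the wrong diastereomer by inverting one stereocenter, fits both against
the identical data and prints the Q-factor comparison and verdict.
"""

import anisofit as af

ensemble = af.make_toy_ensemble(3, seed=1)
populations = af.PopulationSet.uniform(ensemble.conformer_ids)
decoy = af.make_decoy_configuration(ensemble, "C1", configuration_label="RS")

truth = af.SyntheticTruth(
    af.make_true_tensor(5.0e-4, 0.3, orientation_seed=3),
    populations, af.NoiseModel(relative=0.05), seed=3)
data = af.simulate_dataset(ensemble, truth)
decoy_shieldings = af.make_shieldings(decoy, seed=1003)

report = af.discriminate(
    {
        "RR": (ensemble, populations, af.shielding_map(data.shieldings)),
        "RS": (decoy, populations, af.shielding_map(decoy_shieldings)),
    },
    data.rdcs,
    data.rcsas,
    references=[af.EXTERNAL, data.rcsas[0].atom_label],
)

print(f"{'configuration':14s} {'Q(rdc)':>8s} {'Q(rcsa)':>8s} {'Q(combined)':>12s}")
for label in report.verdict:
    blocks = report.fits[label]
    print(f"{label:14s} {blocks['rdc'].q_combined:8.3f} "
          f"{blocks['rcsa:EXTERNAL'].q_combined:8.3f} "
          f"{blocks['combined'].q_combined:12.3f}")
print(f"\nverdict: {report.best}")
print()
print("The true configuration fits the data within the noise (Q ~ 0.05)")
print("while the inverted stereocenter cannot be reconciled with any single")
print("alignment tensor (Q several times larger) - the same contrast used")
print("to assign relative configurations of natural products.")
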