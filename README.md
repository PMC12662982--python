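# anisofit

Stereochemical discrimination of small organic molecules from anisotropic
NMR data: single-alignment-tensor fitting of residual dipolar couplings
(RDC) and residual chemical-shift anisotropies (RCSA, measured as ΔΔRCSA)
over conformer ensembles, Boltzmann selection of ensembles from
quantum-chemistry energies, and CASE-3D-style Akaike selection of conformer
populations from ¹H/¹³C chemical shifts.

## Who this is for

Natural-product and structural chemists who have measured weak-alignment
NMR data (one-bond ¹DCH couplings, ¹³C ΔΔRCSAs, chemical shifts) for a
molecule with unresolved relative configuration, hold DFT-style conformer
ensembles for each candidate diastereomer (geometries, shielding tensors,
energies, computed shifts), and want a reproducible, scriptable way to ask:
*which configuration, and which conformer populations, explain the data?*

## The model

A weakly aligned rigid molecule is described by a traceless symmetric
3×3 order matrix **S** (the alignment/Saupe tensor, 5 independent
components).  Both observables are linear in those components:

```
D_ab   = b_ab · Σ_ij S_ij u_i u_j           b_ab = −(μ0/4π) γ_a γ_b ħ / (2π r³)
RCSA_a = −(2/3) · Σ_ij S_ij σ̃_ij            σ̃ = traceless symmetric shielding
```

For a flexible molecule a single tensor is shared by all conformers and
each observable is the population-weighted average over the ensemble.  The
tensor is found by sigma-weighted SVD least squares; fit quality is the
Q factor `Q = ‖D_exp − D_calc‖ / ‖D_exp‖`, and candidate configurations
are ranked by combined Q — the correct diastereomer fits within the noise,
a wrong one cannot be reconciled with any single tensor.

Ensembles come either from Boltzmann weights
`w_i ∝ exp(−ΔE_i/k_BT)` with a 5% population cutoff (energies in Hartree,
zero-point-corrected or Gibbs), or from the data themselves: conformer
populations are fitted to chemical shifts under a simplex constraint with
per-nucleus linear shift scaling, every conformer subset is scored by
AICc `= n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)`, and the simplest adequate
ensemble wins.

A fully deterministic synthetic-data generator (toy tetrahedral molecules
with two stereocenters and rotatable substituents, random shielding
tensors with 30–200 ppm anisotropies, seeded Gaussian noise, and
stereocenter-inversion decoys) makes every stage testable end to end with
known ground truth.

## Worked example

```bash
python examples/04_discriminate_diastereomers.py
```

```
configuration    Q(rdc)  Q(rcsa)  Q(combined)
RR                0.048    0.020        0.052
RS                0.159    0.810        0.542

verdict: RR
```

Data were simulated from the "RR" ensemble at 5% relative noise; "RS" is
the same molecule with one stereocenter inverted.  RR fits within the
noise floor (Q ≈ 0.05) while no alignment tensor can explain the data with
the RS geometry (combined Q ≈ 0.5) — a tenfold contrast, which is the
discrimination signal used to assign relative configurations.  The other
example scripts walk through back-calculation physics, tensor fitting with
Monte-Carlo error bars, Boltzmann selection, and shift-based (CASE-3D
style) ensemble selection.

There is also a thin CLI over the same library:

```bash
anisofit simulate --out demo --n-conformers 3 --seed 1
anisofit fit --xyz demo/ensemble.xyz --rdc demo/rdc.csv \
             --rcsa demo/rcsa.csv --shielding demo/shielding.csv
anisofit run --config config.yaml --out results/
```

## Layout

- `src/anisofit/` — library: `tensor` (back-calculation physics), `fit`
  (design matrix, SVD fit, Q factors, discrimination), `thermo`
  (Boltzmann weighting and cutoff selection), `case3d` (shift scaling,
  simplex population fits, AICc enumeration), `synthetic` (generator),
  `io` (XYZ/CSV/JSON), `pipeline` + `cli` (orchestration).
- `examples/` — one narrative script per capability.
- `tests/` — unit, property-based (hypothesis) and acceptance suites.
- `docs/methods.md` — model assumptions, conventions, parameter defaults
  and limitations.
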