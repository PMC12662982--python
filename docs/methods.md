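# Methods

## Observables and conventions

The alignment tensor is stored as a traceless symmetric 3×3 matrix and
parametrized by the 5-vector (S_zz, S_xx−S_yy, S_xy, S_xz, S_yz); both
observables are linear maps of that vector, so all fitting reduces to
weighted linear least squares.

Sign conventions are fixed once, package-wide:

* The dipolar interaction constant is
  `b = −(μ0/4π)·γ_a·γ_b·ħ/(2π r³)` in Hz, negative for ¹H–¹³C
  (≈ −23.3 kHz at r = 1.09 Å).  Gyromagnetic ratios and physical
  constants are CODATA-2018, tabulated to full precision in
  `anisofit.constants` (¹H, ¹³C, ¹⁵N, ¹⁹F).
* RCSA is reported on the chemical-shift (δ) scale:
  `RCSA = −(2/3)·Σ S_ij σ̃_ij`, with σ̃ the traceless *symmetric* part of
  the shielding tensor in the conformer frame and the shielding→shift
  sign flip absorbed into the prefactor, converted ppm → ppb.
  The antisymmetric part of a quantum-chemistry shielding tensor does not
  contribute to the observable and is discarded.

A fit followed by back-calculation reproduces its inputs regardless of
these choices; they only matter when comparing tensors across programs.
Internuclear distances come straight from the geometry; a uniform scale
factor on bond vectors (`r_scale`, default 1.0) is exposed as a hook for
effective-versus-equilibrium bond-length conventions but no vibrational
correction is applied.

ΔΔRCSA referencing is applied at fit time: the reference atom's measured
value is subtracted from every other row (sigma propagated in
quadrature), the reference row is dropped, and the reference atom's
*back-calculated* coefficients are subtracted from every design-matrix
row.  The `EXTERNAL` sentinel (solvent-referenced data) subtracts
nothing.  This mirrors how several reference schemes are derived from a
single measurement, and makes the fit invariant (up to noise) to the
reference choice when the data carry no common offset error.

## Ensemble fitting

One tensor is shared by all conformers (single-tensor approximation);
each design-matrix row is the population-weighted average of per-conformer
coefficients, with populations held fixed during the fit.  Rows and
observations are divided by per-datum sigma; an optional "balanced" mode
additionally rescales each data block (RDC, RCSA) to unit rms weighted
observation for users who prefer class-balanced combined fits — the
default remains plain 1/σ.  The minimum-norm solution comes from SVD;
singular values below 1e-10 of the largest are treated as rank loss,
which flags the result and raises a warning rather than failing, since a
rank-deficient minimum-norm tensor can still be diagnostically useful.
At least five observations are required.

Q factors are computed per block on raw units and, for combined fits, on
the sigma-normalized system so Hz and ppb are commensurate.
Uncertainties on Q and on the tensor components come from a seeded noise
Monte Carlo (resampling observations within their sigmas; default 500
draws when requested) rather than analytic covariance claims.

Verdicts order configurations by combined Q, then RDC-only Q, then label;
configurations within 0.005 in combined Q are declared indistinguishable,
since Q differences at the third decimal are below experimental
reproducibility.

## Boltzmann selection

Weights are `w_i ∝ exp(−(E_i − E_min)/(k_B T))` with energies in Hartree;
subtracting the minimum first makes the computation shift-invariant and
overflow-safe.  The default temperature is 298.15 K (thermochemistry
convention); 300 K is exposed as the NMR-measurement preset, and the
temperature used is recorded in every `PopulationSet`.  Selection keeps
conformers with population ≥ cutoff (inclusive, default 5%) and
renormalizes, recording the discarded mass.  Both zero-point-corrected
energies and thermal Gibbs energies are supported; when the two select
different ensembles the pipeline reports both side by side (suffixes
`-zpe` / `-gibbs`) instead of silently preferring one — the disagreement
itself is scientifically meaningful.  Rotamer-duplicate conformers are
not symmetry-collapsed; weights are per supplied structure.

## Shift-based (CASE-3D style) selection

For a candidate conformer subset, populations are fitted by minimizing
`Σ_j w_j²(δ_exp,j − Σ_c p_c δ̃_c,j)²` subject to `p ≥ 0, Σp = 1`.  The
simplex-constrained problem is solved exactly by enumerating active sets
and solving each equality-constrained subproblem through its KKT system —
deterministic and bit-reproducible, with no random restarts (guarded at
16 conformers per subset, far above practical subset sizes).

Computed shifts are rescaled per nucleus class (¹H and ¹³C separately) by
an ordinary-least-squares line fitted from the population-averaged
computed values to experiment — the standard empirical correction for
systematic DFT shift errors.  Scaling and populations are iterated to
convergence (population change < 1e-10, up to 500 iterations; convergence
is linear near simplex vertices, hence the generous cap); a single-pass
mode exists.  A class with fewer than 3 shifts keeps the identity map
with a warning.  ¹H residuals are multiplied by a fixed weight (default
5.0) to offset the ~5–10× smaller proton shift dispersion; a ¹³C-only
mode is available and is the natural choice when proton data are sparse
or their noise model is uncertain.

Subsets are scored by `AIC = n·ln(RSS/n) + 2k` with the small-sample
correction `+2k(k+1)/(n−k−1)` applied by default;
`k = (|subset|−1) + 2×(scaled nucleus classes)`.  RSS below 1e-10 ppm²
(residuals ~1e-5 ppm, far below any meaningful shift precision) is
treated as a perfect fit and reported as −∞; ties — including −∞ ties —
break toward the smaller subset and then id order, so the simplest
adequate ensemble wins.  The selected ensemble is exported with FITTED
populations for subsequent anisotropic fitting.  A DP4-style probability
is deliberately not computed; Akaike selection is the verdict mechanism.

Known behavior: like all AIC-family criteria, AICc overselects with
non-vanishing probability — a spurious extra conformer with a small
fitted weight wins by a small ΔAIC in roughly 5–15% of noisy trials
depending on n.  Recovered populations remain accurate in those cases;
users comparing models within ΔAIC ≈ 2 should treat them as equivalent.

## Synthetic-data generator

The generator emulates the *shape* of a small-molecule anisotropic-NMR
study, not its chemistry:

* **Geometries** — a tetrahedral hydrocarbon with two adjacent
  stereocenters (H + methyl + chain on each) built on a diamond-lattice
  frame from internal coordinates (C–C 1.53 Å, C–H 1.09 Å), with one or
  two rotatable substituent chains sampled at specified dihedrals and a
  seeded Gaussian jitter (default 0.04 Å) on the base geometry.  The
  jitter matters: on the ideal lattice all bonds lie along four
  directions and the RDC design matrix is rank-deficient.  Chain A is
  pre-staggered 60° off-lattice because ideal lattice placement puts
  substituents of the two stereocenters on shared 1,3 sites.  Dihedral
  choices that drive atoms within 1.2 Å of a non-bonded neighbor are
  rejected with an explicit error; the default rotamer angles sample the
  sterically open arc.  Atom counts 23–59 are supported (chain length
  adjusts); sizes around 29 atoms give the ~20 RDC / 9 RCSA data shape,
  59 atoms gives a 19-carbon molecule matching larger natural products.
* **Alignment tensor** — prescribed S_zz (1e-5..1e-2 allowed, 5e-4
  typical) and rhombicity in [0, 2/3], uniformly random orientation.
* **Shieldings** — per carbon: isotropic part uniform in [10, 170] ppm,
  anisotropy log-uniform in [30, 200] ppm (spanning aliphatic to
  carbonyl/aromatic), asymmetry uniform, random orientation; per
  conformer: small reorientation (σ = 10°) and isotropic jitter
  (σ = 2.5 ppm) emulate the conformational dependence of computed
  shieldings.
* **Shifts** — "computed" shifts are a known affine map of isotropic
  shieldings; "experimental" shifts are the population average passed
  through a second known affine distortion (the systematic error that
  shift scaling must undo) plus noise.
* **Noise presets** — RDC 0.5 Hz, ΔΔRCSA 2 ppb, ¹³C shift 0.2 ppm, ¹H
  shift 0.02 ppm; a relative mode sets block sigmas to a fraction of the
  clean rms.  These are presets describing good modern data quality, not
  claims about any particular instrument.  Zero-noise tables record
  sigma 1.0 (neutral uniform weighting) since a measurement row must
  carry a positive uncertainty.
* **Decoy** — one stereocenter is inverted by exchanging its two smallest
  substituent branches (identified from distance-inferred connectivity)
  via reflection through the plane bisecting their bond directions.  The
  reflection is an isometry (bond lengths exact) and an involution
  (applying it twice restores the geometry).  Exchanging two branches,
  rather than reflecting a single branch through the plane of the
  others, is what keeps the inverted geometry clash-free; a residual
  steric overlap below 0.9 Å is still checked and rejected with an error
  naming the atoms.  Decoy shieldings/computed shifts are drawn with
  their own seeds (diastereomers have genuinely different computed
  values).

Everything is a pure function of (parameters, seed); regeneration is
bit-identical.

What passing tests on this generator do **not** show about real data:
real conformers relax rather than rigid-rotate, real shielding tensors
correlate with geometry rather than being random draws, real measurement
errors are not perfectly Gaussian or independent, and real ΔΔRCSA data
can carry common-mode offsets that make the reference choice matter.
The generator is a correctness and calibration instrument, not a
simulator of any specific spectrometer or DFT protocol.

## Pipeline and reproducibility

The `run` pipeline reads one YAML/JSON config, derives Boltzmann
ensembles per available energy kind, optionally runs shift-based
selection (whose chosen ensembles join the candidate list with a
`-case3d` suffix), fits every candidate against the identical
experimental data, and writes a single JSON report embedding the fully
resolved configuration, data counts, and all tensors (5 components plus
eigen-decomposition), Q factors, populations and the verdict.  No
timestamps are written, so identical inputs give byte-identical reports.
Reports round-trip losslessly through the matching reader.  A
configuration whose data are incomplete is flagged and skipped; the rest
are still reported.  CLI exit codes: 0 success, 2 validation/format
error, 3 data completeness.

## Numerical choices, in brief

* SVD rank tolerance 1e-10 × largest singular value; condition number
  reported in every fit.
* Q-verdict tie band 0.005; AIC ties break to smaller subsets.
* Simplex solver feasibility tolerance 1e-10; population iteration
  tolerance 1e-10, cap 500.
* All file round-trips hold to 1e-12 (floats written at full repr
  precision).
* Problem sizes in tests and the acceptance script (29–32-atom
  molecules, 1–6 conformer pools, 50–300 trials per experiment) were
  chosen so each experiment gives stable rates while the whole suite
  stays desk-scale.

## Limitations

* One alignment tensor per ensemble; per-conformer tensors and
  alignment-tensor prediction from molecular shape are out of scope.
* No ¹H–¹H or long-range RDCs beyond the generic pair formula; no
  residual quadrupolar couplings.
* Energies, geometries and shieldings are inputs; nothing quantum-
  chemical is computed here.
* XYZ and CSV are the only geometry/table formats (converter recipes
  from quantum-chemistry outputs are a documentation matter, not code).
* Akaike selection inherits AIC's overselection probability (see above);
  it trades that for not trusting computed energies.
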