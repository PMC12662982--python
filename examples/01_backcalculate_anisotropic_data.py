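"""Back-calculate RDC and RCSA values from a geometry and an alignment tensor.

Builds a one-bond C–H pair and a carbonyl-like shielding tensor, contracts
them with a weak alignment tensor, and prints the resulting observables.
"""

import numpy as np

import anisofit as af
from anisofit.tensor import DipolarPair, back_calc_rcsa, back_calc_rdc, dipolar_constant

# a single C-H bond along z at the standard one-bond distance
conformer = af.Conformer(
    "c1", ("C1", "H1"), ("C", "H"),
    np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.09]]),
)
pair = DipolarPair.from_conformer(conformer, "C1", "H1")
print(f"dipolar constant b(C-H, 1.09 Å) = {dipolar_constant(pair):.1f} Hz")

# axially symmetric alignment, S_zz = 5e-4 (typical weak alignment media)
tensor = af.AlignmentTensor(np.diag([-2.5e-4, -2.5e-4, 5.0e-4]))
rdc = back_calc_rdc(conformer, pair, tensor)
print(f"RDC of the bond along the alignment axis   = {rdc:+.2f} Hz")

# a large-CSA carbon (traceless span 150 ppm) under the same alignment
shielding = af.ShieldingTensor("c1", "C1", np.diag([100.0, -50.0, -50.0]))
rcsa = back_calc_rcsa(shielding, tensor)
print(f"RCSA of a 150 ppm-anisotropy carbon        = {rcsa:+.2f} ppb")

print()
print("The RDC is b scaled by the order along the bond direction; the RCSA")
print("is the tensor-shielding contraction on the chemical-shift scale.")
print("Both are linear in the five independent alignment-tensor components,")
print("which is what makes the single-tensor least-squares fit possible.")
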