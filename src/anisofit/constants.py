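"""Physical constants (CODATA 2018) and the isotope gyromagnetic-ratio table.

All constants are given to full published precision.  Gyromagnetic ratios
are in rad s^-1 T^-1; only spin-1/2 isotopes relevant to one-bond and
long-range dipolar couplings in small organic molecules are tabulated.
"""

from __future__ import annotations

# CODATA 2018
MU0 = 1.25663706212e-6  # vacuum magnetic permeability, N A^-2
HBAR = 1.054571817e-34  # reduced Planck constant, J s
KB = 1.380649e-23  # Boltzmann constant, J K^-1 (exact, SI 2019)
HARTREE_TO_J = 4.3597447222071e-18  # Hartree energy, J
AVOGADRO = 6.02214076e23  # mol^-1 (exact)

ANGSTROM = 1.0e-10  # m

#: gyromagnetic ratios, rad s^-1 T^-1
GYROMAGNETIC: dict[str, float] = {
    "1H": 2.6752218744e8,
    "13C": 6.728284e7,
    "15N": -2.7126e7,
    "19F": 2.518148e8,
}

#: default NMR isotope assumed for each element in dipolar couplings
ELEMENT_TO_ISOTOPE: dict[str, str] = {
    "H": "1H",
    "C": "13C",
    "N": "15N",
    "F": "19F",
}

#: thermochemistry convention temperature, K
T_STANDARD = 298.15
#: typical NMR measurement temperature preset, K
T_NMR = 300.0


def gamma_for_element(element: str) -> float:
    """Gyromagnetic ratio of the default NMR isotope of *element*.

    Raises
    ------
    KeyError
        If the element has no tabulated spin-1/2 isotope.
    """
    try:
        return GYROMAGNETIC[ELEMENT_TO_ISOTOPE[element]]
    except KeyError:
        raise KeyError(
            f"no gyromagnetic ratio tabulated for element {element!r}; "
            f"known: {sorted(ELEMENT_TO_ISOTOPE)}"
        ) from None
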