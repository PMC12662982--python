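"""Alignment-tensor physics: dipolar couplings and RCSA back-calculation.

An alignment (Saupe) tensor ``S`` is a dimensionless, traceless, symmetric
3×3 order matrix with five independent components.  For a weakly aligned
molecule the residual dipolar coupling of a spin pair and the residual
chemical-shift anisotropy of a nucleus are both linear in those five
components:

    D_ab   = b_ab · Σ_ij S_ij u_i u_j            (u: internuclear unit vector)
    RCSA_a = −(2/3) · Σ_ij S_ij σ̃_ij · 1000      (σ̃: traceless symmetric
                                                  shielding, ppm → ppb)

with the dipolar interaction constant

    b_ab = −(μ0/4π) γ_a γ_b ħ / (2π r³)   [Hz].

Sign conventions, fixed here once for the whole package: ``b`` carries the
physical negative sign for like-sign gyromagnetic ratios, and RCSA is
reported on the chemical-shift (δ) scale, i.e. the shielding→shift sign
flip is already applied in the −(2/3) prefactor.  Fits followed by
back-calculation reproduce their inputs independently of these choices;
they only matter when comparing tensors with other software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .errors import AnisofitError, ValidationError
from .records import EXTERNAL, Conformer, ShieldingTensor

__all__ = [
    "AlignmentTensor",
    "DipolarPair",
    "SAUPE_BASIS",
    "dipolar_constant",
    "back_calc_rdc",
    "back_calc_rcsa",
    "delta_delta_rcsa",
]


def _basis() -> np.ndarray:
    """Basis matrices for the 5-vector (S_zz, S_xx−S_yy, S_xy, S_xz, S_yz).

    ``saupe = Σ_k s_k · SAUPE_BASIS[k]`` for any traceless symmetric S.
    """
    b = np.zeros((5, 3, 3))
    # s0 = S_zz  (with S_xx = S_yy = −S_zz/2)
    b[0] = np.diag([-0.5, -0.5, 1.0])
    # s1 = S_xx − S_yy (at fixed S_zz): S_xx = +1/2, S_yy = −1/2
    b[1] = np.diag([0.5, -0.5, 0.0])
    b[2][0, 1] = b[2][1, 0] = 1.0  # S_xy
    b[3][0, 2] = b[3][2, 0] = 1.0  # S_xz
    b[4][1, 2] = b[4][2, 1] = 1.0  # S_yz
    return b


SAUPE_BASIS = _basis()
SAUPE_BASIS.setflags(write=False)


@dataclass(frozen=True)
class AlignmentTensor:
    """Traceless symmetric order matrix (dimensionless)."""

    saupe: np.ndarray  # (3, 3)

    def __post_init__(self):
        m = np.asarray(self.saupe, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError(f"Saupe matrix shape {m.shape}, expected (3, 3)")
        if not np.all(np.isfinite(m)):
            raise ValidationError("Saupe matrix contains non-finite entries")
        if np.max(np.abs(m - m.T)) > 1e-12:
            raise ValidationError("Saupe matrix not symmetric to 1e-12")
        if abs(np.trace(m)) > 1e-12 * max(1.0, np.max(np.abs(m))):
            raise ValidationError("Saupe matrix not traceless to 1e-12")
        object.__setattr__(self, "saupe", m)

    @classmethod
    def from_vector(cls, s: np.ndarray) -> "AlignmentTensor":
        """Assemble from the 5-vector (S_zz, S_xx−S_yy, S_xy, S_xz, S_yz)."""
        s = np.asarray(s, dtype=float)
        if s.shape != (5,):
            raise ValidationError(f"expected 5-vector, got shape {s.shape}")
        return cls(np.einsum("k,kij->ij", s, SAUPE_BASIS))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AlignmentTensor":
        """Symmetrize and project out the trace of an arbitrary 3×3 matrix."""
        m = np.asarray(m, dtype=float)
        sym = 0.5 * (m + m.T)
        return cls(sym - np.eye(3) * (np.trace(sym) / 3.0))

    def to_vector(self) -> np.ndarray:
        """The 5 independent components (S_zz, S_xx−S_yy, S_xy, S_xz, S_yz)."""
        m = self.saupe
        return np.array(
            [m[2, 2], m[0, 0] - m[1, 1], m[0, 1], m[0, 2], m[1, 2]]
        )

    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues and eigenvectors ordered |S_zz| ≥ |S_yy| ≥ |S_xx|.

        Returns ``(values, vectors)`` with values as (S_xx, S_yy, S_zz) and
        vectors as columns in the same order.
        """
        vals, vecs = np.linalg.eigh(self.saupe)
        order = np.argsort(np.abs(vals))  # ascending magnitude -> (xx, yy, zz)
        return vals[order], vecs[:, order]

    @property
    def magnitude(self) -> float:
        """|S_zz| of the principal frame (generalized degree of order scale)."""
        vals, _ = self.principal()
        return float(abs(vals[2]))

    @property
    def rhombicity(self) -> float:
        """R = (S_xx − S_yy) / S_zz in the principal frame, in [0, 2/3]."""
        vals, _ = self.principal()
        if vals[2] == 0.0:
            return 0.0
        return float(abs((vals[0] - vals[1]) / vals[2]))

    def rotated(self, rotation: np.ndarray) -> "AlignmentTensor":
        """The tensor expressed after rotating the frame by matrix *R*."""
        r = np.asarray(rotation, dtype=float)
        return AlignmentTensor.from_matrix(r @ self.saupe @ r.T)


@dataclass(frozen=True)
class DipolarPair:
    """A dipolar-coupled spin pair within one conformer."""

    label_a: str
    label_b: str
    gamma_a: float  # rad s^-1 T^-1
    gamma_b: float
    r_vector: np.ndarray  # Å

    def __post_init__(self):
        v = np.asarray(self.r_vector, dtype=float)
        if v.shape != (3,):
            raise ValidationError("r_vector must be a 3-vector")
        object.__setattr__(self, "r_vector", v)
        if np.linalg.norm(v) <= 0.5:
            raise ValidationError(
                f"pair {self.label_a}-{self.label_b}: internuclear distance "
                f"{np.linalg.norm(v):.3f} Å implausibly short (must be > 0.5 Å)"
            )

    @classmethod
    def from_conformer(
        cls, conformer: Conformer, label_a: str, label_b: str,
        r_scale: float = 1.0,
    ) -> "DipolarPair":
        """Build a pair from a conformer's geometry and the isotope table.

        *r_scale* uniformly scales the internuclear distance (hook for
        effective vs equilibrium bond lengths; default 1.0 = geometry as-is).
        """
        va = conformer.position(label_a)
        vb = conformer.position(label_b)
        try:
            ga = constants.gamma_for_element(conformer.element(label_a))
            gb = constants.gamma_for_element(conformer.element(label_b))
        except KeyError as exc:
            raise AnisofitError(str(exc)) from exc
        return cls(label_a, label_b, ga, gb, (vb - va) * r_scale)


def dipolar_constant(pair: DipolarPair) -> float:
    """Maximum dipolar interaction constant b of *pair*, Hz.

    ``b = −(μ0/4π) γ_a γ_b ħ / (2π r³)``; for a ¹H–¹³C bond at 1.09 Å this
    is about −23.3 kHz.
    """
    r_m = float(np.linalg.norm(pair.r_vector)) * constants.ANGSTROM
    return (
        -(constants.MU0 / (4.0 * np.pi))
        * pair.gamma_a * pair.gamma_b * constants.HBAR
        / (2.0 * np.pi * r_m**3)
    )


def rdc_coefficients(pair: DipolarPair) -> np.ndarray:
    """Row of the linear map from the 5 tensor components to this pair's RDC.

    ``D = rdc_coefficients(pair) @ tensor.to_vector()`` in Hz.
    """
    r = np.linalg.norm(pair.r_vector)
    if r == 0.0:
        raise AnisofitError(
            f"pair {pair.label_a}-{pair.label_b}: zero-length internuclear vector"
        )
    u = pair.r_vector / r
    b = dipolar_constant(pair)
    return b * np.einsum("kij,i,j->k", SAUPE_BASIS, u, u)


def back_calc_rdc(
    conformer: Conformer, pair: DipolarPair, tensor: AlignmentTensor
) -> float:
    """Back-calculated RDC of *pair* under *tensor*, Hz.

    The conformer argument is accepted for interface symmetry and label
    validation; the geometry enters through the pair's internuclear vector.
    """
    conformer.index(pair.label_a)
    conformer.index(pair.label_b)
    return float(rdc_coefficients(pair) @ tensor.to_vector())


def rcsa_coefficients(shielding: ShieldingTensor) -> np.ndarray:
    """Row of the linear map from the 5 tensor components to this atom's RCSA (ppb)."""
    st = shielding.symmetric_traceless  # ppm
    return -(2.0 / 3.0) * 1.0e3 * np.einsum("kij,ij->k", SAUPE_BASIS, st)


def back_calc_rcsa(shielding: ShieldingTensor, tensor: AlignmentTensor) -> float:
    """Back-calculated RCSA on the chemical-shift scale, ppb."""
    return float(rcsa_coefficients(shielding) @ tensor.to_vector())


def delta_delta_rcsa(
    values: dict[str, float], reference_spec: str
) -> dict[str, float]:
    """Reference a map of per-atom RCSA values (ppb) to one atom.

    Subtracts the reference atom's value from every entry, so the reference
    itself becomes exactly 0 (callers exclude it from fitting residuals).
    ``reference_spec == EXTERNAL`` subtracts nothing.
    """
    if reference_spec == EXTERNAL:
        return dict(values)
    if reference_spec not in values:
        raise AnisofitError(
            f"ΔΔRCSA reference {reference_spec!r} absent from value map "
            f"(have {sorted(values)})"
        )
    ref = values[reference_spec]
    return {label: v - ref for label, v in values.items()}
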