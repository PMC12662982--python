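"""Typed records shared across the pipeline.

The join key everywhere is the NMR-style atom label ("C2", "H3a", "S-CH3"):
geometries, shielding tensors, experimental tables and chemical shifts all
refer to atoms by these labels, mirroring how NMR data are reported per
assigned position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

#: sentinel reference for ΔΔRCSA data referenced to an external signal
#: (e.g. the solvent carbon): the reference's back-calculated RCSA is zero.
EXTERNAL = "EXTERNAL"

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Br", "I", "Se", "Fe", "Zn",
}


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what} contains non-finite values")


@dataclass(frozen=True)
class Conformer:
    """One labeled Cartesian geometry (coordinates in Å)."""

    conformer_id: str
    atom_labels: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self):
        object.__setattr__(self, "atom_labels", tuple(self.atom_labels))
        object.__setattr__(self, "elements", tuple(self.elements))
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        n = len(self.atom_labels)
        if not (len(self.elements) == n and coords.shape == (n, 3)):
            raise ValidationError(
                f"conformer {self.conformer_id!r}: labels/elements/coords "
                f"lengths disagree ({n}, {len(self.elements)}, {coords.shape})"
            )
        if len(set(self.atom_labels)) != n:
            raise ValidationError(
                f"conformer {self.conformer_id!r}: duplicate atom labels"
            )
        _check_finite(coords, f"conformer {self.conformer_id!r} coordinates")
        for el in self.elements:
            if el not in _ELEMENTS:
                raise ValidationError(
                    f"conformer {self.conformer_id!r}: unknown element {el!r}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    def index(self, label: str) -> int:
        """Index of *label*, raising ``KeyError`` with context if absent."""
        try:
            return self.atom_labels.index(label)
        except ValueError:
            raise KeyError(
                f"atom label {label!r} not in conformer {self.conformer_id!r}"
            ) from None

    def position(self, label: str) -> np.ndarray:
        return self.coords[self.index(label)]

    def element(self, label: str) -> str:
        return self.elements[self.index(label)]


@dataclass(frozen=True)
class ConformationalEnsemble:
    """A set of conformers of one candidate configuration.

    All conformers share one atom-label scheme in identical order, so a
    label refers to the same chemical position in every member.  Optional
    ``populations`` are fractional weights summing to one.
    """

    configuration_label: str
    conformers: tuple[Conformer, ...]
    populations: tuple[float, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "conformers", tuple(self.conformers))
        if not self.conformers:
            raise ValidationError("ensemble must contain at least one conformer")
        ref = self.conformers[0]
        for c in self.conformers[1:]:
            if c.atom_labels != ref.atom_labels:
                raise ValidationError(
                    f"ensemble {self.configuration_label!r}: conformer "
                    f"{c.conformer_id!r} has a different atom labeling than "
                    f"{ref.conformer_id!r}"
                )
            if c.elements != ref.elements:
                raise ValidationError(
                    f"ensemble {self.configuration_label!r}: conformer "
                    f"{c.conformer_id!r} has different elements"
                )
        ids = [c.conformer_id for c in self.conformers]
        if len(set(ids)) != len(ids):
            raise ValidationError(
                f"ensemble {self.configuration_label!r}: duplicate conformer ids"
            )
        if self.populations is not None:
            pops = tuple(float(p) for p in self.populations)
            object.__setattr__(self, "populations", pops)
            if len(pops) != len(self.conformers):
                raise ValidationError("populations length != number of conformers")
            if any(p < 0 for p in pops):
                raise ValidationError("populations must be non-negative")
            if abs(sum(pops) - 1.0) > 1e-9:
                raise ValidationError(
                    f"populations sum to {sum(pops)!r}, expected 1 within 1e-9"
                )

    @property
    def atom_labels(self) -> tuple[str, ...]:
        return self.conformers[0].atom_labels

    @property
    def conformer_ids(self) -> tuple[str, ...]:
        return tuple(c.conformer_id for c in self.conformers)

    def __len__(self) -> int:
        return len(self.conformers)

    def __getitem__(self, conformer_id: str) -> Conformer:
        for c in self.conformers:
            if c.conformer_id == conformer_id:
                return c
        raise KeyError(
            f"conformer {conformer_id!r} not in ensemble "
            f"{self.configuration_label!r}"
        )

    def subset(self, conformer_ids: Sequence[str]) -> "ConformationalEnsemble":
        """Sub-ensemble restricted to *conformer_ids* (populations dropped)."""
        return ConformationalEnsemble(
            configuration_label=self.configuration_label,
            conformers=tuple(self[cid] for cid in conformer_ids),
        )


@dataclass(frozen=True)
class RDCDatum:
    """One experimental residual dipolar coupling, Hz."""

    label_a: str
    label_b: str
    value: float  # Hz
    sigma: float  # Hz

    def __post_init__(self):
        if self.label_a == self.label_b:
            raise ValidationError(f"RDC labels identical: {self.label_a!r}")
        if not (self.sigma > 0):
            raise ValidationError(
                f"RDC {self.label_a}-{self.label_b}: sigma must be > 0, "
                f"got {self.sigma!r}"
            )
        if not math.isfinite(self.value):
            raise ValidationError(f"RDC {self.label_a}-{self.label_b}: non-finite value")

    @property
    def key(self) -> tuple[str, str]:
        return (self.label_a, self.label_b)


@dataclass(frozen=True)
class RCSADatum:
    """One experimental (ΔΔ)RCSA, ppb, with its reference scheme.

    ``reference_spec`` is either another atom label (that atom's
    back-calculated RCSA is subtracted during fitting) or :data:`EXTERNAL`,
    meaning the reference contributes zero back-calculated RCSA.
    """

    atom_label: str
    value: float  # ppb
    sigma: float  # ppb
    reference_spec: str = EXTERNAL

    def __post_init__(self):
        if not (self.sigma > 0):
            raise ValidationError(
                f"RCSA {self.atom_label}: sigma must be > 0, got {self.sigma!r}"
            )
        if not math.isfinite(self.value):
            raise ValidationError(f"RCSA {self.atom_label}: non-finite value")

    @property
    def key(self) -> str:
        return self.atom_label


@dataclass(frozen=True)
class ShieldingTensor:
    """A computed nuclear shielding tensor for one (conformer, atom), ppm.

    The raw tensor may be non-symmetric (quantum-chemistry outputs often
    are); only its symmetric part contributes to observable RCSA and is
    used in back-calculation.
    """

    conformer_id: str
    atom_label: str
    sigma_matrix: np.ndarray  # (3, 3), ppm

    def __post_init__(self):
        m = np.asarray(self.sigma_matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError(
                f"shielding {self.conformer_id}/{self.atom_label}: "
                f"matrix shape {m.shape}, expected (3, 3)"
            )
        _check_finite(m, f"shielding {self.conformer_id}/{self.atom_label}")
        object.__setattr__(self, "sigma_matrix", m)

    @property
    def isotropic(self) -> float:
        """Isotropic shielding, ppm (one third of the trace)."""
        return float(np.trace(self.sigma_matrix)) / 3.0

    @property
    def symmetric_traceless(self) -> np.ndarray:
        """Traceless symmetric part — the only part visible to alignment."""
        s = 0.5 * (self.sigma_matrix + self.sigma_matrix.T)
        return s - np.eye(3) * (np.trace(s) / 3.0)

    @property
    def anisotropy(self) -> float:
        """CSA span Δσ = σ33 − (σ11 + σ22)/2 of the symmetric part, ppm."""
        ev = np.sort(np.linalg.eigvalsh(0.5 * (self.sigma_matrix + self.sigma_matrix.T)))
        return float(ev[2] - 0.5 * (ev[0] + ev[1]))

    @property
    def key(self) -> tuple[str, str]:
        return (self.conformer_id, self.atom_label)


ShieldingMap = Mapping[tuple[str, str], ShieldingTensor]


def shielding_map(records: Sequence[ShieldingTensor]) -> dict[tuple[str, str], ShieldingTensor]:
    """Index shielding records by (conformer_id, atom_label), rejecting duplicates."""
    out: dict[tuple[str, str], ShieldingTensor] = {}
    for rec in records:
        if rec.key in out:
            raise ValidationError(f"duplicate shielding record for {rec.key}")
        out[rec.key] = rec
    return out


@dataclass(frozen=True)
class EnergyRecord:
    """One conformer energy, Hartree."""

    VALID_KINDS = ("E_ZPE", "G_THERMAL", "E_ELEC")

    conformer_id: str
    energy_kind: str
    value: float  # Hartree

    def __post_init__(self):
        if self.energy_kind not in self.VALID_KINDS:
            raise ValidationError(
                f"energy kind {self.energy_kind!r} not in {self.VALID_KINDS}"
            )
        if not math.isfinite(self.value):
            raise ValidationError(
                f"energy {self.conformer_id}/{self.energy_kind}: non-finite"
            )


@dataclass(frozen=True)
class ShiftDatum:
    """One experimental chemical shift with per-conformer computed values, ppm."""

    atom_label: str
    nucleus: str  # "H1" or "C13"
    value_exp: float  # ppm
    computed: Mapping[str, float] = field(default_factory=dict)  # conformer_id -> ppm

    def __post_init__(self):
        if self.nucleus not in ("H1", "C13"):
            raise ValidationError(f"nucleus must be 'H1' or 'C13', got {self.nucleus!r}")
        expected_el = "H" if self.nucleus == "H1" else "C"
        lead = self.atom_label.lstrip("0123456789")[:1].upper()
        if lead and lead != expected_el and not self.atom_label.upper().startswith(expected_el):
            # labels like "S-CH3" carry the observed nucleus later in the
            # string; only flag a hard mismatch (e.g. nucleus C13 on "H5")
            if self.atom_label[:1].upper() in ("H", "C") and self.atom_label[:1].upper() != expected_el:
                raise ValidationError(
                    f"shift {self.atom_label!r}: label inconsistent with nucleus "
                    f"{self.nucleus}"
                )
        if not math.isfinite(self.value_exp):
            raise ValidationError(f"shift {self.atom_label}: non-finite value")
        object.__setattr__(self, "computed", dict(self.computed))
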