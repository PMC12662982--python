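"""Boltzmann populations from conformer energies and population-cutoff selection.

Energies arrive in Hartree (as quantum-chemistry codes print them); weights
are ``w_i ∝ exp(−(E_i − E_min)/(k_B T))``.  Two energy kinds are the usual
selection criteria: electronic energy plus zero-point correction (E_ZPE)
and thermal Gibbs free energy (G_THERMAL) — ensembles selected by the two
can differ, which is scientifically meaningful and preserved downstream by
labeling each selection with its source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import constants
from .errors import DataCompletenessError, ValidationError
from .records import ConformationalEnsemble, EnergyRecord

__all__ = ["PopulationSet", "boltzmann_weights", "select_by_population"]

POPULATION_SOURCES = ("E_ZPE", "G_THERMAL", "E_ELEC", "UNIFORM", "FITTED")


@dataclass(frozen=True)
class PopulationSet:
    """Fractional conformer weights with their provenance."""

    weights: Mapping[str, float]  # conformer_id -> weight
    temperature: float = constants.T_STANDARD  # K
    source: str = "UNIFORM"

    def __post_init__(self):
        w = dict(self.weights)
        object.__setattr__(self, "weights", w)
        if self.source not in POPULATION_SOURCES:
            raise ValidationError(
                f"population source {self.source!r} not in {POPULATION_SOURCES}"
            )
        if any(v < 0 for v in w.values()):
            raise ValidationError("populations must be non-negative")
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"populations sum to {total!r}, expected 1 within 1e-9"
            )

    def __getitem__(self, conformer_id: str) -> float:
        return self.weights[conformer_id]

    @classmethod
    def uniform(cls, conformer_ids: Sequence[str],
                temperature: float = constants.T_STANDARD) -> "PopulationSet":
        n = len(conformer_ids)
        return cls({cid: 1.0 / n for cid in conformer_ids}, temperature, "UNIFORM")

    @classmethod
    def fitted(cls, weights: Mapping[str, float],
               temperature: float = constants.T_STANDARD) -> "PopulationSet":
        return cls(weights, temperature, "FITTED")


def boltzmann_weights(
    records: Sequence[EnergyRecord],
    kind: str,
    temperature: float = constants.T_STANDARD,
) -> PopulationSet:
    """Normalized Boltzmann weights from energies of one *kind* (Hartree).

    Weights are computed relative to the minimum energy, so an overall
    energy shift leaves them unchanged; *temperature* is in kelvin.
    """
    if temperature <= 0:
        raise ValidationError(f"temperature must be > 0 K, got {temperature!r}")
    energies: dict[str, float] = {}
    for rec in records:
        if rec.energy_kind != kind:
            continue
        if rec.conformer_id in energies:
            raise ValidationError(
                f"duplicate {kind} energy for conformer {rec.conformer_id!r}"
            )
        energies[rec.conformer_id] = rec.value
    if not energies:
        raise DataCompletenessError(f"no energy records of kind {kind!r}")
    e_min = min(energies.values())
    beta = constants.HARTREE_TO_J / (constants.KB * temperature)  # per Hartree
    raw = {cid: math.exp(-(e - e_min) * beta) for cid, e in energies.items()}
    total = sum(raw.values())
    return PopulationSet(
        {cid: v / total for cid, v in raw.items()}, temperature, kind
    )


def select_by_population(
    ensemble: ConformationalEnsemble,
    populations: PopulationSet,
    cutoff: float = 0.05,
) -> tuple[ConformationalEnsemble, PopulationSet, float]:
    """Keep conformers with weight ≥ *cutoff* (inclusive) and renormalize.

    Returns ``(sub_ensemble, renormalized_populations, discarded_mass)``.
    The inclusive boundary means a conformer at exactly the cutoff survives.
    """
    if not (0.0 <= cutoff < 1.0):
        raise ValidationError(f"cutoff must be in [0, 1), got {cutoff!r}")
    missing = [cid for cid in ensemble.conformer_ids
               if cid not in populations.weights]
    if missing:
        raise DataCompletenessError(
            f"populations missing for conformers {missing}"
        )
    keep = [cid for cid in ensemble.conformer_ids
            if populations[cid] >= cutoff]
    if not keep:
        raise ValidationError(
            f"cutoff {cutoff} removes every conformer of "
            f"{ensemble.configuration_label!r}"
        )
    kept_mass = sum(populations[cid] for cid in keep)
    renorm = PopulationSet(
        {cid: populations[cid] / kept_mass for cid in keep},
        populations.temperature,
        populations.source,
    )
    return ensemble.subset(keep), renorm, 1.0 - kept_mass
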