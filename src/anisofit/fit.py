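"""Single-tensor ensemble fitting of RDC and ΔΔRCSA data.

The model: one alignment tensor is shared by all conformers of an ensemble
(single-tensor approximation) and each observable is the population-weighted
average of the per-conformer back-calculated values.  Both RDC and RCSA are
linear in the five independent tensor components, so the fit is a weighted
linear least-squares problem solved by singular value decomposition.

Fit quality is summarized by the Q factor

    Q = sqrt(Σ (exp − calc)²) / sqrt(Σ exp²),

computed per data block on raw units and, for combined RDC+RCSA fits, on
sigma-normalized values so Hz and ppb are commensurate.  Candidate relative
configurations are ranked by combined Q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    AnisofitError,
    DataCompletenessError,
    UnderDeterminedError,
    ValidationError,
)
from .records import (
    EXTERNAL,
    ConformationalEnsemble,
    RCSADatum,
    RDCDatum,
    ShieldingMap,
)
from .tensor import AlignmentTensor, DipolarPair, rcsa_coefficients, rdc_coefficients
from .thermo import PopulationSet

__all__ = [
    "Design",
    "FitResult",
    "DiscriminationReport",
    "build_design_matrix",
    "fit_alignment_tensor",
    "fit_data",
    "q_factor",
    "reference_rcsas",
    "discriminate",
]

#: singular values below this fraction of the largest are treated as rank loss
RANK_TOL = 1e-10
#: combined-Q differences below this are experimentally indistinguishable
Q_TIE_TOL = 0.005


def q_factor(exp: Sequence[float], calc: Sequence[float]) -> float:
    """Normalized rms deviation between experimental and back-calculated data."""
    e = np.asarray(exp, dtype=float)
    c = np.asarray(calc, dtype=float)
    if e.shape != c.shape or e.ndim != 1 or e.size < 1:
        raise ValidationError("q_factor requires equal-length 1-D inputs, n >= 1")
    denom = float(np.sqrt(np.sum(e**2)))
    if denom == 0.0:
        raise ValidationError("Q factor undefined: experimental vector is all zero")
    return float(np.sqrt(np.sum((e - c) ** 2)) / denom)


@dataclass
class Design:
    """Weighted linear system mapping 5 tensor components to observations.

    ``matrix`` and ``observations`` are sigma-weighted (and optionally
    block-balanced); ``raw_matrix``/``raw_observations`` are in physical
    units (Hz, ppb) for per-block Q factors and reporting.
    """

    matrix: np.ndarray  # (n, 5), weighted
    observations: np.ndarray  # (n,), weighted
    raw_matrix: np.ndarray  # (n, 5), physical units
    raw_observations: np.ndarray  # (n,)
    sigmas: np.ndarray  # (n,)
    blocks: tuple[str, ...]  # "rdc" | "rcsa" per row
    labels: tuple[str, ...]  # human-readable datum ids

    @property
    def n_data(self) -> int:
        return len(self.observations)


def _rdc_row(
    ensemble: ConformationalEnsemble,
    populations: PopulationSet,
    datum: RDCDatum,
    r_scale: float,
) -> np.ndarray:
    row = np.zeros(5)
    for conf in ensemble.conformers:
        pair = DipolarPair.from_conformer(conf, datum.label_a, datum.label_b, r_scale)
        row += populations[conf.conformer_id] * rdc_coefficients(pair)
    return row


def _rcsa_row(
    ensemble: ConformationalEnsemble,
    populations: PopulationSet,
    atom_label: str,
    shieldings: ShieldingMap,
) -> np.ndarray:
    row = np.zeros(5)
    missing = []
    for conf in ensemble.conformers:
        key = (conf.conformer_id, atom_label)
        if key not in shieldings:
            missing.append(key)
            continue
        row += populations[conf.conformer_id] * rcsa_coefficients(shieldings[key])
    if missing:
        raise DataCompletenessError(
            f"missing shielding tensors for {missing} "
            f"(ensemble {ensemble.configuration_label!r})"
        )
    return row


def build_design_matrix(
    ensemble: ConformationalEnsemble,
    populations: PopulationSet,
    data: Sequence[RDCDatum | RCSADatum],
    shieldings: ShieldingMap | None = None,
    weighting: str = "sigma",
    r_scale: float = 1.0,
) -> Design:
    """Assemble the population-averaged, sigma-weighted design matrix.

    Row *i* holds the population-weighted average over conformers of the
    per-conformer linear coefficients mapping the 5 tensor components to
    datum *i*.  ΔΔRCSA rows have the reference atom's coefficients
    subtracted (nothing for ``EXTERNAL``).  Rows and observations are
    divided by the per-datum sigma; ``weighting="balanced"`` additionally
    rescales each data block to unit rms observation.
    """
    if weighting not in ("sigma", "balanced"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    missing_pop = [cid for cid in ensemble.conformer_ids
                   if cid not in populations.weights]
    if missing_pop:
        raise DataCompletenessError(f"populations missing for {missing_pop}")

    rows, obs, sig, blocks, labels = [], [], [], [], []
    for datum in data:
        if isinstance(datum, RDCDatum):
            rows.append(_rdc_row(ensemble, populations, datum, r_scale))
            obs.append(datum.value)
            sig.append(datum.sigma)
            blocks.append("rdc")
            labels.append(f"rdc:{datum.label_a}-{datum.label_b}")
        elif isinstance(datum, RCSADatum):
            if shieldings is None:
                raise DataCompletenessError(
                    "RCSA data require shielding tensors, none supplied"
                )
            if datum.reference_spec != EXTERNAL and datum.atom_label == datum.reference_spec:
                warnings.warn(
                    f"RCSA row for reference atom {datum.atom_label!r} is "
                    "identically zero; excluded from the fit",
                    stacklevel=2,
                )
                continue
            row = _rcsa_row(ensemble, populations, datum.atom_label, shieldings)
            if datum.reference_spec != EXTERNAL:
                row = row - _rcsa_row(
                    ensemble, populations, datum.reference_spec, shieldings
                )
            rows.append(row)
            obs.append(datum.value)
            sig.append(datum.sigma)
            blocks.append("rcsa")
            labels.append(f"rcsa:{datum.atom_label}")
        else:
            raise ValidationError(f"unsupported datum type {type(datum).__name__}")

    raw_matrix = np.array(rows).reshape(len(rows), 5)
    raw_obs = np.array(obs)
    sigmas = np.array(sig)
    w = 1.0 / sigmas
    if weighting == "balanced":
        wm = raw_matrix * w[:, None]
        wo = raw_obs * w
        for block in set(blocks):
            mask = np.array([b == block for b in blocks])
            rms = float(np.sqrt(np.mean(wo[mask] ** 2)))
            if rms > 0:
                w[mask] /= rms
    return Design(
        matrix=raw_matrix * w[:, None],
        observations=raw_obs * w,
        raw_matrix=raw_matrix,
        raw_observations=raw_obs,
        sigmas=sigmas,
        blocks=tuple(blocks),
        labels=tuple(labels),
    )


@dataclass
class FitResult:
    """Outcome of a single-tensor fit on one data block (or combination)."""

    tensor: AlignmentTensor
    labels: tuple[str, ...]
    blocks: tuple[str, ...]
    exp: np.ndarray  # physical units
    calc: np.ndarray  # physical units
    sigmas: np.ndarray
    q_rdc: float | None
    q_rcsa: float | None
    q_combined: float
    n_rdc: int
    n_rcsa: int
    condition_number: float
    rank: int
    rank_deficient: bool = False
    q_combined_se: float | None = None  # noise Monte-Carlo spread
    tensor_se: np.ndarray | None = None  # per-component spread (5-vector)

    @property
    def residuals(self) -> np.ndarray:
        return self.exp - self.calc

    @property
    def n_data(self) -> int:
        return len(self.exp)

    def to_dict(self) -> dict:
        vals, vecs = self.tensor.principal()
        return {
            "tensor": {
                "vector": self.tensor.to_vector().tolist(),
                "eigenvalues": vals.tolist(),
                "eigenvectors": vecs.tolist(),
            },
            "labels": list(self.labels),
            "blocks": list(self.blocks),
            "exp": self.exp.tolist(),
            "calc": self.calc.tolist(),
            "sigmas": self.sigmas.tolist(),
            "q_rdc": self.q_rdc,
            "q_rcsa": self.q_rcsa,
            "q_combined": self.q_combined,
            "n_rdc": self.n_rdc,
            "n_rcsa": self.n_rcsa,
            "condition_number": self.condition_number,
            "rank": self.rank,
            "rank_deficient": self.rank_deficient,
            "q_combined_se": self.q_combined_se,
            "tensor_se": None if self.tensor_se is None else self.tensor_se.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            tensor=AlignmentTensor.from_vector(np.array(d["tensor"]["vector"])),
            labels=tuple(d["labels"]),
            blocks=tuple(d["blocks"]),
            exp=np.array(d["exp"]),
            calc=np.array(d["calc"]),
            sigmas=np.array(d["sigmas"]),
            q_rdc=d["q_rdc"],
            q_rcsa=d["q_rcsa"],
            q_combined=d["q_combined"],
            n_rdc=d["n_rdc"],
            n_rcsa=d["n_rcsa"],
            condition_number=d["condition_number"],
            rank=d["rank"],
            rank_deficient=d["rank_deficient"],
            q_combined_se=d.get("q_combined_se"),
            tensor_se=None if d.get("tensor_se") is None else np.array(d["tensor_se"]),
        )


def _solve(matrix: np.ndarray, observations: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Minimum-norm least squares via SVD; returns (solution, singulars, rank)."""
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    rank = int(np.sum(s > RANK_TOL * s[0])) if s[0] > 0 else 0
    keep = s > RANK_TOL * (s[0] if s[0] > 0 else 1.0)
    s_inv = np.divide(1.0, s, out=np.zeros_like(s), where=keep)
    x = vt.T @ (s_inv * (u.T @ observations))
    return x, s, rank


def fit_alignment_tensor(
    design: Design | np.ndarray,
    observations: np.ndarray | None = None,
    mc_draws: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Fit the alignment tensor to a weighted design by SVD least squares.

    Accepts either a :class:`Design` or a bare ``(n × 5)`` weighted matrix
    with its observation vector.  At least five observations are required;
    a numerical rank below five raises a warning and flags the result
    rather than failing silently.  With ``mc_draws > 0`` the observations
    are resampled within their sigmas to estimate the spread of Q and of
    the tensor components.
    """
    if isinstance(design, np.ndarray):
        if observations is None:
            raise ValidationError("observations required with a bare matrix")
        matrix = np.asarray(design, dtype=float)
        design = Design(
            matrix=matrix,
            observations=np.asarray(observations, dtype=float),
            raw_matrix=matrix,
            raw_observations=np.asarray(observations, dtype=float),
            sigmas=np.ones(len(observations)),
            blocks=("rdc",) * len(observations),
            labels=tuple(f"row{i}" for i in range(len(observations))),
        )
    if design.n_data < 5:
        raise UnderDeterminedError(
            f"{design.n_data} observations cannot determine 5 tensor components"
        )
    x, singulars, rank = _solve(design.matrix, design.observations)
    rank_deficient = rank < 5
    if rank_deficient:
        warnings.warn(
            f"design matrix numerically rank-deficient (rank {rank} < 5); "
            "the fitted tensor is the minimum-norm solution",
            stacklevel=2,
        )
    cond = float(singulars[0] / singulars[-1]) if singulars[-1] > 0 else float("inf")
    tensor = AlignmentTensor.from_vector(x)
    calc = design.raw_matrix @ x
    blocks = np.array(design.blocks)
    rdc_mask = blocks == "rdc"
    rcsa_mask = blocks == "rcsa"
    q_rdc = (
        q_factor(design.raw_observations[rdc_mask], calc[rdc_mask])
        if rdc_mask.any() else None
    )
    q_rcsa = (
        q_factor(design.raw_observations[rcsa_mask], calc[rcsa_mask])
        if rcsa_mask.any() else None
    )
    q_combined = q_factor(design.observations, design.matrix @ x)

    q_se = None
    tensor_se = None
    if mc_draws > 0:
        rng = np.random.default_rng(seed)
        # net per-row weight (sigma and any block balancing), recovered from
        # the ratio of weighted to raw row norms so zero observations are safe
        raw_norms = np.linalg.norm(design.raw_matrix, axis=1)
        w_norms = np.linalg.norm(design.matrix, axis=1)
        weights = np.where(raw_norms > 0, w_norms / np.where(raw_norms > 0, raw_norms, 1.0),
                           1.0 / design.sigmas)
        qs = np.empty(mc_draws)
        xs = np.empty((mc_draws, 5))
        for i in range(mc_draws):
            noisy_raw = design.raw_observations + rng.normal(0, design.sigmas)
            noisy = noisy_raw * weights
            xi, _, _ = _solve(design.matrix, noisy)
            xs[i] = xi
            qs[i] = q_factor(noisy, design.matrix @ xi)
        q_se = float(np.std(qs))
        tensor_se = np.std(xs, axis=0)

    return FitResult(
        tensor=tensor,
        labels=design.labels,
        blocks=design.blocks,
        exp=design.raw_observations.copy(),
        calc=calc,
        sigmas=design.sigmas.copy(),
        q_rdc=q_rdc,
        q_rcsa=q_rcsa,
        q_combined=q_combined,
        n_rdc=int(rdc_mask.sum()),
        n_rcsa=int(rcsa_mask.sum()),
        condition_number=cond,
        rank=rank,
        rank_deficient=rank_deficient,
        q_combined_se=q_se,
        tensor_se=tensor_se,
    )


def fit_data(
    ensemble: ConformationalEnsemble,
    populations: PopulationSet,
    data: Sequence[RDCDatum | RCSADatum],
    shieldings: ShieldingMap | None = None,
    weighting: str = "sigma",
    mc_draws: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Convenience wrapper: build the design matrix and fit in one call."""
    design = build_design_matrix(ensemble, populations, data, shieldings, weighting)
    return fit_alignment_tensor(design, mc_draws=mc_draws, seed=seed)


def reference_rcsas(
    rcsas: Sequence[RCSADatum], reference_spec: str
) -> list[RCSADatum]:
    """Re-reference an (EXTERNAL-referenced) ΔΔRCSA table to one atom.

    Subtracts the reference atom's measured value from every other row,
    drops the reference row itself, and propagates the reference's sigma in
    quadrature.  With ``EXTERNAL`` the table is returned unchanged.
    """
    if reference_spec == EXTERNAL:
        return list(rcsas)
    by_label = {d.atom_label: d for d in rcsas}
    if reference_spec not in by_label:
        raise AnisofitError(
            f"reference atom {reference_spec!r} has no measured RCSA row"
        )
    ref = by_label[reference_spec]
    out = []
    for d in rcsas:
        if d.atom_label == reference_spec:
            continue
        out.append(
            RCSADatum(
                atom_label=d.atom_label,
                value=d.value - ref.value,
                sigma=float(np.hypot(d.sigma, ref.sigma)),
                reference_spec=reference_spec,
            )
        )
    return out


@dataclass
class DiscriminationReport:
    """Per-configuration fit results and the ranked verdict.

    ``fits`` maps configuration label → block name → :class:`FitResult`;
    block names are ``"rdc"``, ``"rcsa:<reference>"`` and ``"combined"``.
    ``verdict`` lists configuration labels from best (lowest combined Q) to
    worst; configurations whose combined Q is within ``Q_TIE_TOL`` of the
    leader are recorded in ``indistinguishable``.
    """

    fits: dict[str, dict[str, FitResult]]
    verdict: list[str]
    indistinguishable: list[str]
    populations: dict[str, dict[str, float]]
    failed: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)  # resolved config, seeds, versions

    @property
    def best(self) -> str | None:
        return self.verdict[0] if self.verdict else None

    def to_dict(self) -> dict:
        return {
            "fits": {
                label: {block: fr.to_dict() for block, fr in blocks.items()}
                for label, blocks in self.fits.items()
            },
            "verdict": list(self.verdict),
            "indistinguishable": list(self.indistinguishable),
            "populations": {k: dict(v) for k, v in self.populations.items()},
            "failed": dict(self.failed),
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminationReport":
        return cls(
            fits={
                label: {block: FitResult.from_dict(fr) for block, fr in blocks.items()}
                for label, blocks in d["fits"].items()
            },
            verdict=list(d["verdict"]),
            indistinguishable=list(d["indistinguishable"]),
            populations={k: dict(v) for k, v in d["populations"].items()},
            failed=dict(d.get("failed", {})),
            meta=dict(d.get("meta", {})),
        )


def discriminate(
    configurations: Mapping[
        str, tuple[ConformationalEnsemble, PopulationSet, ShieldingMap]
    ],
    rdcs: Sequence[RDCDatum],
    rcsas: Sequence[RCSADatum],
    references: Sequence[str] = (EXTERNAL,),
    weighting: str = "sigma",
    combined_reference: str | None = None,
    mc_draws: int = 0,
    seed: int | None = None,
) -> DiscriminationReport:
    """Fit identical experimental data against every candidate configuration.

    For each configuration an RDC-only fit, one ΔΔRCSA fit per reference
    scheme, and a combined RDC+ΔΔRCSA fit are performed (the combined fit
    uses ``combined_reference``, defaulting to the first reference).  The
    verdict orders configurations by combined Q, breaking ties by RDC-only
    Q and then label; a configuration whose data are incomplete is flagged
    in ``failed`` while the rest are still reported.
    """
    if len(configurations) < 2:
        warnings.warn("fewer than two configurations: no comparison possible",
                      stacklevel=2)
    if combined_reference is None:
        combined_reference = references[0] if references else EXTERNAL

    fits: dict[str, dict[str, FitResult]] = {}
    failed: dict[str, str] = {}
    populations: dict[str, dict[str, float]] = {}
    for label, (ensemble, pops, shieldings) in configurations.items():
        populations[label] = dict(pops.weights)
        try:
            blocks: dict[str, FitResult] = {}
            if rdcs:
                blocks["rdc"] = fit_data(
                    ensemble, pops, list(rdcs), weighting=weighting,
                    mc_draws=mc_draws, seed=seed,
                )
            for ref in references:
                refd = reference_rcsas(rcsas, ref)
                blocks[f"rcsa:{ref}"] = fit_data(
                    ensemble, pops, refd, shieldings, weighting=weighting,
                    mc_draws=mc_draws, seed=seed,
                )
            combined_data = list(rdcs) + reference_rcsas(rcsas, combined_reference)
            blocks["combined"] = fit_data(
                ensemble, pops, combined_data, shieldings, weighting=weighting,
                mc_draws=mc_draws, seed=seed,
            )
            fits[label] = blocks
        except (DataCompletenessError, UnderDeterminedError) as exc:
            failed[label] = str(exc)

    def sort_key(label: str):
        blocks = fits[label]
        q_rdc = blocks["rdc"].q_combined if "rdc" in blocks else float("inf")
        return (blocks["combined"].q_combined, q_rdc, label)

    verdict = sorted(fits, key=sort_key)
    indistinguishable: list[str] = []
    if verdict:
        q_best = fits[verdict[0]]["combined"].q_combined
        indistinguishable = [
            lbl for lbl in verdict
            if fits[lbl]["combined"].q_combined - q_best <= Q_TIE_TOL
        ]
        if len(indistinguishable) < 2:
            indistinguishable = []
    return DiscriminationReport(
        fits=fits,
        verdict=verdict,
        indistinguishable=indistinguishable,
        populations=populations,
        failed=failed,
    )
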