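"""Akaike-based selection of conformer populations from chemical shifts.

The approach (computer-assisted 3D structure elucidation, "CASE-3D" style)
treats the experimental ¹H/¹³C chemical shifts as a population-weighted
mixture of per-conformer computed shifts.  For every candidate conformer
subset the populations are fitted by simplex-constrained least squares
(p ≥ 0, Σp = 1) jointly with a per-nucleus-class linear rescaling of the
computed shifts (the usual empirical correction of systematic DFT shift
errors), and subsets are ranked by an Akaike information criterion that
trades fit quality against the number of free parameters.  Unlike
energy-based (Boltzmann) selection, the data alone decide which conformers
carry weight.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .errors import DataCompletenessError, ProtocolError, ValidationError
from .records import ConformationalEnsemble, ShiftDatum
from .thermo import PopulationSet

__all__ = [
    "ModelScore",
    "Case3DReport",
    "simplex_lstsq",
    "scale_computed_shifts",
    "fit_populations",
    "aic_score",
    "enumerate_models",
    "case3d_select",
]

#: default multiplier on ¹H residuals, compensating the ~5–10× smaller
#: shift dispersion of protons relative to carbons
DEFAULT_H_WEIGHT = 5.0

MAX_MODELS = 1_000_000


def simplex_lstsq(
    a: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Minimize ``||W(Ap − y)||²`` subject to ``p ≥ 0`` and ``Σp = 1``.

    Exact deterministic solver: every support set of the (small) simplex is
    solved as an equality-constrained least-squares problem via its KKT
    system, infeasible candidates are discarded, and the feasible optimum
    is returned.  Intended for the handfuls of conformers typical of
    model enumeration (guarded at 16 columns).

    Returns ``(p, weighted_rss)``.
    """
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = a.shape
    if k > 16:
        raise ValidationError(
            f"simplex_lstsq supports at most 16 columns, got {k}"
        )
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    aw = a * w[:, None]
    yw = y * w

    best_obj = math.inf
    best_p: np.ndarray | None = None
    for size in range(1, k + 1):
        for support in combinations(range(k), size):
            idx = list(support)
            asub = aw[:, idx]
            # KKT for min ||asub q - yw||^2 s.t. 1'q = 1
            h = asub.T @ asub
            kkt = np.zeros((size + 1, size + 1))
            kkt[:size, :size] = 2.0 * h
            kkt[:size, size] = 1.0
            kkt[size, :size] = 1.0
            rhs = np.concatenate([2.0 * asub.T @ yw, [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
            q = sol[:size]
            if np.any(q < -1e-10) or not np.all(np.isfinite(q)):
                continue
            q = np.clip(q, 0.0, None)
            total = q.sum()
            if total <= 0:
                continue
            q /= total
            resid = asub @ q - yw
            obj = float(resid @ resid)
            if obj < best_obj - 1e-14:
                best_obj = obj
                best_p = np.zeros(k)
                best_p[idx] = q
    if best_p is None:  # pragma: no cover - defensive
        raise ValidationError("simplex least squares found no feasible point")
    return best_p, best_obj


def _class_of(datum: ShiftDatum) -> str:
    return datum.nucleus


def scale_computed_shifts(
    shifts: Sequence[ShiftDatum],
    averaged_computed: Sequence[float],
) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Linear rescaling of computed shifts onto the experimental scale.

    Fits one ordinary-least-squares line per nucleus class (¹H and ¹³C
    separately) mapping the ensemble-averaged computed shifts to the
    experimental ones, and applies it to the computed values.  A class with
    fewer than 3 points keeps the identity map (with a warning).

    Returns ``(scaled_values, {class: (slope, intercept)})``.
    """
    exp = np.array([s.value_exp for s in shifts])
    calc = np.asarray(averaged_computed, dtype=float)
    if calc.shape != exp.shape:
        raise ValidationError("averaged computed values must align with shifts")
    classes = [_class_of(s) for s in shifts]
    scaled = calc.copy()
    params: dict[str, tuple[float, float]] = {}
    for cls in sorted(set(classes)):
        mask = np.array([c == cls for c in classes])
        if mask.sum() < 3:
            warnings.warn(
                f"nucleus class {cls}: fewer than 3 shifts, scaling disabled "
                "(identity map)", stacklevel=2,
            )
            params[cls] = (1.0, 0.0)
            continue
        slope, intercept = np.polyfit(calc[mask], exp[mask], 1)
        params[cls] = (float(slope), float(intercept))
        scaled[mask] = slope * calc[mask] + intercept
    return scaled, params


def _shift_arrays(
    subset: Sequence[str], shifts: Sequence[ShiftDatum]
) -> tuple[np.ndarray, np.ndarray]:
    """(n_shifts × n_conformers) computed matrix and experimental vector."""
    missing = [
        (s.atom_label, cid) for s in shifts for cid in subset
        if cid not in s.computed
    ]
    if missing:
        raise DataCompletenessError(
            f"computed shifts missing for (atom, conformer) pairs {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    a = np.array([[s.computed[cid] for cid in subset] for s in shifts])
    y = np.array([s.value_exp for s in shifts])
    return a, y


def fit_populations(
    subset: Sequence[str],
    shifts: Sequence[ShiftDatum],
    h_weight: float = DEFAULT_H_WEIGHT,
    nucleus: str = "both",
    scale: bool = True,
    iterate: bool = True,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[dict[str, float], float, dict[str, tuple[float, float]]]:
    """Fit simplex-constrained conformer populations to chemical shifts.

    Minimizes ``Σ_j w_j² (δ_exp,j − Σ_c p_c δ̃_calc,c,j)²`` with ¹H
    residuals multiplied by *h_weight* and per-class linear shift scaling
    (δ̃) refitted against the current population average until convergence
    (``iterate=False`` scales once from the uniform average).  ``nucleus``
    restricts the data to ``"c13"`` or ``"h1"`` only.

    Returns ``(populations, weighted_rss_ppm2, scale_params)``.
    """
    if not subset:
        raise ValidationError("subset must contain at least one conformer")
    if nucleus not in ("both", "c13", "h1"):
        raise ValidationError(f"nucleus mode {nucleus!r} invalid")
    if nucleus != "both":
        wanted = "C13" if nucleus == "c13" else "H1"
        shifts = [s for s in shifts if s.nucleus == wanted]
    if not shifts:
        raise DataCompletenessError("no shifts left after nucleus filtering")
    a, y = _shift_arrays(subset, shifts)
    w = np.array([h_weight if s.nucleus == "H1" else 1.0 for s in shifts])

    p = np.full(len(subset), 1.0 / len(subset))
    params: dict[str, tuple[float, float]] = {
        cls: (1.0, 0.0) for cls in sorted({s.nucleus for s in shifts})
    }
    n_passes = max_iter if (scale and iterate) else 1
    for _ in range(n_passes):
        if scale:
            avg = a @ p
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, params = scale_computed_shifts(shifts, avg)
            slopes = np.array([params[s.nucleus][0] for s in shifts])
            intercepts = np.array([params[s.nucleus][1] for s in shifts])
            a_scaled = a * slopes[:, None] + intercepts[:, None]
        else:
            a_scaled = a
        p_new, rss = simplex_lstsq(a_scaled, y, w)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    if scale:
        # report the scaling consistent with the converged populations
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, params = scale_computed_shifts(shifts, a @ p)
        slopes = np.array([params[s.nucleus][0] for s in shifts])
        intercepts = np.array([params[s.nucleus][1] for s in shifts])
        a_scaled = a * slopes[:, None] + intercepts[:, None]
    resid = (a_scaled @ p - y) * w
    rss = float(resid @ resid)
    populations = {cid: float(p[i]) for i, cid in enumerate(subset)}
    return populations, rss, params


def aic_score(
    rss: float, n: int, k: int, corrected: bool = True
) -> float:
    """Akaike information criterion for a Gaussian least-squares model.

    ``AIC = n·ln(rss/n) + 2k``; with ``corrected=True`` the small-sample
    correction ``+ 2k(k+1)/(n−k−1)`` is added (the default, appropriate for
    the ~30-shift datasets this method targets).  A perfect fit
    (``rss == 0``) returns ``−inf``.
    """
    if rss < 0:
        raise ValidationError("rss must be >= 0")
    if n <= k + 1:
        raise ValidationError(
            f"AIC{'c' if corrected else ''} requires n > k + 1 (n={n}, k={k})"
        )
    if rss == 0.0:
        warnings.warn("perfect fit (rss = 0): AIC reported as -inf", stacklevel=2)
        return -math.inf
    aic = n * math.log(rss / n) + 2 * k
    if corrected:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


@dataclass
class ModelScore:
    """One scored conformer subset: the CASE-3D selection unit."""

    subset: tuple[str, ...]
    populations: dict[str, float]
    scale_params: dict[str, tuple[float, float]]
    rss: float  # weighted, ppm^2
    n: int
    k: int
    aic: float
    rank: int | None = None

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset),
            "populations": dict(self.populations),
            "scale_params": {c: list(v) for c, v in self.scale_params.items()},
            "rss": self.rss,
            "n": self.n,
            "k": self.k,
            "aic": self.aic,
            "rank": self.rank,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelScore":
        return cls(
            subset=tuple(d["subset"]),
            populations=dict(d["populations"]),
            scale_params={c: (v[0], v[1]) for c, v in d["scale_params"].items()},
            rss=d["rss"], n=d["n"], k=d["k"], aic=d["aic"], rank=d.get("rank"),
        )


def _free_parameters(subset_size: int, scale_params: Mapping[str, tuple[float, float]],
                     scale: bool) -> int:
    # (size-1) population freedoms + slope/intercept per scaled nucleus class
    n_scaled = sum(1 for v in scale_params.values() if scale) if scale else 0
    return (subset_size - 1) + 2 * n_scaled


def enumerate_models(
    ensemble: ConformationalEnsemble | Sequence[str],
    shifts: Sequence[ShiftDatum],
    max_subset_size: int,
    h_weight: float = DEFAULT_H_WEIGHT,
    nucleus: str = "both",
    scale: bool = True,
    iterate: bool = True,
    corrected: bool = True,
    rss_floor: float = 1e-10,
) -> list[ModelScore]:
    """Score every conformer subset of size 1..max_subset_size by AIC.

    Returns models ranked ascending by AIC; ties (including the −inf
    sentinel of numerically perfect fits, i.e. rss below *rss_floor* ppm²)
    are broken toward the smaller subset and then by id order, so the
    simplest adequate ensemble wins.  The total number of subsets is
    guarded at 10⁶ — lower ``max_subset_size`` if exceeded.
    """
    ids = (
        list(ensemble.conformer_ids)
        if isinstance(ensemble, ConformationalEnsemble)
        else list(ensemble)
    )
    if max_subset_size > len(ids):
        raise ValidationError(
            f"max_subset_size {max_subset_size} exceeds ensemble size {len(ids)}"
        )
    total = sum(math.comb(len(ids), s) for s in range(1, max_subset_size + 1))
    if total > MAX_MODELS:
        raise ValidationError(
            f"{total} candidate subsets exceed the {MAX_MODELS} guard; "
            "lower max_subset_size"
        )
    models: list[ModelScore] = []
    for size in range(1, max_subset_size + 1):
        for subset in combinations(ids, size):
            pops, rss, params = fit_populations(
                subset, shifts, h_weight=h_weight, nucleus=nucleus,
                scale=scale, iterate=iterate,
            )
            used = [s for s in shifts if nucleus == "both"
                    or s.nucleus == ("C13" if nucleus == "c13" else "H1")]
            n = len(used)
            k = _free_parameters(size, params, scale)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                aic = aic_score(0.0 if rss < rss_floor else rss, n, k,
                                corrected=corrected)
            models.append(ModelScore(
                subset=tuple(subset), populations=pops, scale_params=params,
                rss=rss, n=n, k=k, aic=aic,
            ))
    models.sort(key=lambda m: (m.aic, len(m.subset), m.subset))
    for i, m in enumerate(models):
        m.rank = i + 1
    return models


@dataclass
class Case3DReport:
    """Per-configuration best (S1) and runner-up (S2) models plus verdict."""

    models: dict[str, list[ModelScore]]  # configuration -> ranked (top kept)
    s1: dict[str, ModelScore]
    s2: dict[str, ModelScore | None]
    verdict: list[str]  # configurations by best AIC, ascending
    selected: dict[str, tuple[ConformationalEnsemble, PopulationSet]]

    @property
    def best(self) -> str | None:
        return self.verdict[0] if self.verdict else None


def case3d_select(
    configurations: Mapping[
        str, tuple[ConformationalEnsemble, Sequence[ShiftDatum]]
    ],
    max_subset_size: int = 3,
    h_weight: float = DEFAULT_H_WEIGHT,
    nucleus: str = "both",
    scale: bool = True,
    iterate: bool = True,
    corrected: bool = True,
    keep_models: int = 10,
) -> Case3DReport:
    """Rank candidate configurations by their best-AIC conformer ensemble.

    Every configuration must carry the identical experimental shift set
    (the computed values differ, the measurements do not).  The selected
    ensemble of each configuration is exported as a sub-ensemble with a
    FITTED :class:`~anisofit.thermo.PopulationSet`, ready for anisotropic
    (RDC/RCSA) fitting.
    """
    exp_sets = {
        label: sorted((s.atom_label, s.nucleus, s.value_exp) for s in shifts)
        for label, (_, shifts) in configurations.items()
    }
    first = next(iter(exp_sets.values()), None)
    for label, es in exp_sets.items():
        if es != first:
            raise ProtocolError(
                f"configuration {label!r} has a different experimental shift "
                "set than the others; CASE-3D comparison requires identical data"
            )

    models: dict[str, list[ModelScore]] = {}
    s1: dict[str, ModelScore] = {}
    s2: dict[str, ModelScore | None] = {}
    selected: dict[str, tuple[ConformationalEnsemble, PopulationSet]] = {}
    for label, (ensemble, shifts) in configurations.items():
        ranked = enumerate_models(
            ensemble, shifts, min(max_subset_size, len(ensemble)),
            h_weight=h_weight, nucleus=nucleus, scale=scale,
            iterate=iterate, corrected=corrected,
        )
        models[label] = ranked[:keep_models]
        s1[label] = ranked[0]
        s2[label] = ranked[1] if len(ranked) > 1 else None
        sub = ensemble.subset(s1[label].subset)
        selected[label] = (sub, PopulationSet.fitted(s1[label].populations))
    verdict = sorted(models, key=lambda lbl: (s1[lbl].aic, lbl))
    return Case3DReport(models=models, s1=s1, s2=s2, verdict=verdict,
                        selected=selected)
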