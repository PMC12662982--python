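"""Readers and writers for the on-disk artifacts.

Geometries travel as standard multi-record XYZ (optionally with a 5th
column of NMR-style atom labels or a sidecar label map); data tables are
CSV with fixed headers; reports are JSON.  All values are stored in
canonical units — Hz, ppb, ppm, Hartree, Å — and every reader returns
validated typed records only.

CSV schemas
-----------
rdc        label_a,label_b,value_hz,sigma_hz
rcsa       label,value_ppb,sigma_ppb,reference
shielding  conformer_id,label,s_xx,s_xy,s_xz,s_yx,s_yy,s_yz,s_zx,s_zy,s_zz
energy     conformer_id,kind,hartree
shift      label,nucleus,exp_ppm,<one column per conformer_id>
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .fit import DiscriminationReport, FitResult
from .records import (
    Conformer,
    ConformationalEnsemble,
    EnergyRecord,
    RCSADatum,
    RDCDatum,
    ShieldingTensor,
    ShiftDatum,
)

__all__ = [
    "read_xyz_ensemble",
    "write_xyz_ensemble",
    "read_table",
    "write_table",
    "write_report",
    "read_report",
]

_SHIELD_COLS = ["s_xx", "s_xy", "s_xz", "s_yx", "s_yy", "s_yz", "s_zx", "s_zy", "s_zz"]


def read_xyz_ensemble(
    path: str | Path,
    configuration_label: str,
    label_map: Sequence[str] | None = None,
) -> ConformationalEnsemble:
    """Read a multi-record XYZ file into an ensemble.

    Atom labels come from a 5th column if present, else from *label_map*
    (one label per atom, applied to every record), else are generated as
    element+index ("C1", "H2", ...).  The comment line may carry
    ``id=<conformer_id>``; ids default to the 1-based record order.
    Records must agree in atom count, elements and labels.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    conformers: list[Conformer] = []
    i = 0
    rec = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        rec += 1
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise FormatError(
                f"{path}: record {rec}: expected atom count, got {lines[i]!r}"
            ) from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        conformer_id = str(rec)
        for token in comment.split():
            if token.startswith("id="):
                conformer_id = token[3:]
        elements, labels, coords = [], [], []
        for j in range(natoms):
            k = i + 2 + j
            if k >= len(lines):
                raise FormatError(f"{path}: record {rec}: truncated atom block")
            parts = lines[k].split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: record {rec}, atom line {j + 1}: "
                    f"expected 'element x y z [label]', got {lines[k]!r}"
                )
            elements.append(parts[0])
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise FormatError(
                    f"{path}: record {rec}, atom line {j + 1}: bad coordinates"
                ) from None
            if len(parts) >= 5:
                labels.append(parts[4])
        if labels and len(labels) != natoms:
            raise FormatError(
                f"{path}: record {rec}: label column present on only some atoms"
            )
        if not labels:
            if label_map is not None:
                if len(label_map) != natoms:
                    raise FormatError(
                        f"{path}: record {rec}: label map has {len(label_map)} "
                        f"entries for {natoms} atoms"
                    )
                labels = list(label_map)
            else:
                counts: dict[str, int] = {}
                for el in elements:
                    counts[el] = counts.get(el, 0) + 1
                    labels.append(f"{el}{counts[el]}")
        try:
            conformers.append(
                Conformer(conformer_id, tuple(labels), tuple(elements),
                          np.array(coords))
            )
        except ValidationError as exc:
            raise FormatError(f"{path}: record {rec}: {exc}") from exc
        i += 2 + natoms
    if not conformers:
        raise FormatError(f"{path}: no XYZ records found")
    first = conformers[0]
    for c in conformers[1:]:
        if c.atom_labels != first.atom_labels or c.elements != first.elements:
            raise FormatError(
                f"{path}: record with id {c.conformer_id!r} has a different "
                f"atom count/ordering/labeling than record {first.conformer_id!r}"
            )
    return ConformationalEnsemble(configuration_label, tuple(conformers))


def write_xyz_ensemble(ensemble: ConformationalEnsemble, path: str | Path) -> None:
    """Write an ensemble as multi-record XYZ with a label column."""
    path = Path(path)
    out = []
    for conf in ensemble.conformers:
        out.append(str(conf.n_atoms))
        out.append(f"id={conf.conformer_id} configuration={ensemble.configuration_label}")
        for el, lab, xyz in zip(conf.elements, conf.atom_labels, conf.coords):
            out.append(f"{el:2s} {xyz[0]:18.12f} {xyz[1]:18.12f} {xyz[2]:18.12f} {lab}")
    path.write_text("\n".join(out) + "\n")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path, schema: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: schema {schema!r} requires columns {missing} "
            f"(found {list(df.columns)})"
        )


def _no_duplicates(keys: list, path, schema: str) -> None:
    seen = set()
    for k in keys:
        if k in seen:
            raise ValidationError(f"{path}: duplicate {schema} record for {k!r}")
        seen.add(k)


def read_table(path: str | Path, schema: str) -> list:
    """Read one CSV data table into typed records (canonical units)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty:
        warnings.warn(f"{path}: table has no data rows", stacklevel=2)
    if schema == "rdc":
        _require_columns(df, ["label_a", "label_b", "value_hz", "sigma_hz"], path, schema)
        recs = [
            RDCDatum(str(r.label_a), str(r.label_b), float(r.value_hz), float(r.sigma_hz))
            for r in df.itertuples()
        ]
        _no_duplicates([r.key for r in recs], path, schema)
        return recs
    if schema == "rcsa":
        _require_columns(df, ["label", "value_ppb", "sigma_ppb", "reference"], path, schema)
        recs = [
            RCSADatum(str(r.label), float(r.value_ppb), float(r.sigma_ppb),
                      str(r.reference))
            for r in df.itertuples()
        ]
        _no_duplicates([r.key for r in recs], path, schema)
        return recs
    if schema == "shielding":
        _require_columns(df, ["conformer_id", "label"] + _SHIELD_COLS, path, schema)
        recs = [
            ShieldingTensor(
                str(r.conformer_id), str(r.label),
                np.array([getattr(r, c) for c in _SHIELD_COLS], dtype=float).reshape(3, 3),
            )
            for r in df.itertuples()
        ]
        _no_duplicates([r.key for r in recs], path, schema)
        return recs
    if schema == "energy":
        _require_columns(df, ["conformer_id", "kind", "hartree"], path, schema)
        recs = [
            EnergyRecord(str(r.conformer_id), str(r.kind), float(r.hartree))
            for r in df.itertuples()
        ]
        _no_duplicates([(r.conformer_id, r.energy_kind) for r in recs], path, schema)
        return recs
    if schema == "shift":
        _require_columns(df, ["label", "nucleus", "exp_ppm"], path, schema)
        conf_cols = [c for c in df.columns if c not in ("label", "nucleus", "exp_ppm")]
        recs = [
            ShiftDatum(
                str(row["label"]), str(row["nucleus"]), float(row["exp_ppm"]),
                {c: float(row[c]) for c in conf_cols},
            )
            for _, row in df.iterrows()
        ]
        _no_duplicates([(r.atom_label, r.nucleus) for r in recs], path, schema)
        return recs
    raise ValidationError(f"unknown table schema {schema!r}")


def write_table(records: Sequence, path: str | Path, schema: str) -> None:
    """Write typed records back to their CSV schema (inverse of read_table)."""
    path = Path(path)
    if schema == "rdc":
        df = pd.DataFrame(
            [(r.label_a, r.label_b, r.value, r.sigma) for r in records],
            columns=["label_a", "label_b", "value_hz", "sigma_hz"],
        )
    elif schema == "rcsa":
        df = pd.DataFrame(
            [(r.atom_label, r.value, r.sigma, r.reference_spec) for r in records],
            columns=["label", "value_ppb", "sigma_ppb", "reference"],
        )
    elif schema == "shielding":
        df = pd.DataFrame(
            [
                (r.conformer_id, r.atom_label, *r.sigma_matrix.ravel())
                for r in records
            ],
            columns=["conformer_id", "label"] + _SHIELD_COLS,
        )
    elif schema == "energy":
        df = pd.DataFrame(
            [(r.conformer_id, r.energy_kind, r.value) for r in records],
            columns=["conformer_id", "kind", "hartree"],
        )
    elif schema == "shift":
        conf_ids: list[str] = []
        for r in records:
            for cid in r.computed:
                if cid not in conf_ids:
                    conf_ids.append(cid)
        df = pd.DataFrame(
            [
                (r.atom_label, r.nucleus, r.value_exp,
                 *[r.computed.get(cid, np.nan) for cid in conf_ids])
                for r in records
            ],
            columns=["label", "nucleus", "exp_ppm"] + conf_ids,
        )
    else:
        raise ValidationError(f"unknown table schema {schema!r}")
    # repr-precision floats so read(write(x)) == x to 1e-12 and beyond
    df.to_csv(path, index=False, float_format="%.17g")


def write_report(report: DiscriminationReport, path: str | Path) -> None:
    """Serialize a discrimination report to JSON (lossless round-trip)."""
    for label, blocks in report.fits.items():
        for block, fr in blocks.items():
            if not isinstance(fr, FitResult) or fr.tensor is None:
                raise ValidationError(
                    f"report integrity: configuration {label!r} block "
                    f"{block!r} lacks a fitted tensor"
                )
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def read_report(path: str | Path) -> DiscriminationReport:
    """Read back a JSON report written by :func:`write_report`."""
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    return DiscriminationReport.from_dict(d)
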