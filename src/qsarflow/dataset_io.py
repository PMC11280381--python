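"""Compound tables: reading, writing, activity-unit conversion and splitting.

A :class:`Dataset` is an ordered collection of :class:`CompoundRecord`
objects sharing a common descriptor vocabulary.  Records carry either an
observed activity (IC50 with a unit, or pIC50 directly) or none at all, in
which case they are *candidates* — designed molecules whose activity the
fitted model will predict.

The pIC50 convention used throughout is the negative decadic logarithm of
the molar IC50: pIC50 = -log10(IC50 [mol/L]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ParseError,
    ValidationError,
)

__all__ = [
    "CompoundRecord",
    "Dataset",
    "ic50_to_pic50",
    "read_compound_table",
    "write_compound_table",
    "split_dataset",
]

#: molar scale factors for the supported IC50 units
_UNIT_SCALE = {"nM": 1e-9, "uM": 1e-6, "µM": 1e-6, "M": 1.0}

#: tolerance for agreement between a supplied pIC50 and a converted IC50
_ACTIVITY_AGREEMENT_TOL = 1e-6


def ic50_to_pic50(value: float, unit: str) -> float:
    """Convert an IC50 to pIC50 = -log10(IC50 in mol/L).

    Parameters
    ----------
    value
        Positive IC50 in the given unit.
    unit
        One of ``nM``, ``uM``/``µM`` or ``M``.
    """
    if unit not in _UNIT_SCALE:
        raise ConfigurationError(
            f"unknown IC50 unit {unit!r}; expected one of {sorted(set(_UNIT_SCALE))}"
        )
    if not (value > 0) or not math.isfinite(value):
        raise ValidationError(f"IC50 must be a positive finite number, got {value!r}")
    return -math.log10(value * _UNIT_SCALE[unit])


@dataclass
class CompoundRecord:
    """One compound: identifier, optional structure, descriptors, activity."""

    id: str
    descriptors: dict[str, float]
    smiles: str | None = None
    ic50: float | None = None
    ic50_unit: str | None = None
    pic50: float | None = None

    def __post_init__(self):
        for name, value in self.descriptors.items():
            if not math.isfinite(value):
                raise ValidationError(
                    f"compound {self.id!r}: descriptor {name!r} is not finite ({value!r})"
                )
        if self.ic50 is not None:
            if self.ic50_unit is None:
                raise ValidationError(
                    f"compound {self.id!r}: ic50 given without a unit"
                )
            converted = ic50_to_pic50(self.ic50, self.ic50_unit)
            if self.pic50 is not None:
                if abs(self.pic50 - converted) > _ACTIVITY_AGREEMENT_TOL:
                    raise ValidationError(
                        f"compound {self.id!r}: pic50 {self.pic50} disagrees with "
                        f"ic50 {self.ic50} {self.ic50_unit} (-> {converted:.6f})"
                    )
            else:
                self.pic50 = converted

    @property
    def activity(self) -> float | None:
        """Observed pIC50, or None for candidate records."""
        return self.pic50

    @property
    def is_candidate(self) -> bool:
        return self.pic50 is None


# role labels a record may carry after splitting
ROLES = ("train", "test", "candidate")


@dataclass
class Dataset:
    """Ordered compound records with a shared descriptor vocabulary."""

    records: list[CompoundRecord]
    descriptor_names: list[str]
    role_labels: list[str | None] = field(default_factory=list)

    def __post_init__(self):
        if not self.role_labels:
            self.role_labels = [
                "candidate" if r.is_candidate else None for r in self.records
            ]
        self.validate()

    def validate(self) -> None:
        if len(self.role_labels) != len(self.records):
            raise ValidationError("role_labels length does not match records")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate compound id {rec.id!r}")
            seen.add(rec.id)
            missing = [n for n in self.descriptor_names if n not in rec.descriptors]
            if missing:
                raise ValidationError(
                    f"compound {rec.id!r} is missing descriptors {missing} (ragged row)"
                )
        for role, rec in zip(self.role_labels, self.records):
            if role not in ROLES and role is not None:
                raise ValidationError(f"unknown role label {role!r}")
            if role in ("train", "test") and rec.is_candidate:
                raise ValidationError(
                    f"compound {rec.id!r} has role {role!r} but no observed activity"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, role: str) -> "Dataset":
        """Records carrying the given role label, order preserved."""
        recs = [r for r, lab in zip(self.records, self.role_labels) if lab == role]
        return Dataset(recs, list(self.descriptor_names), [role] * len(recs))

    def X(self, role: str | None = None, columns: list[str] | None = None) -> pd.DataFrame:
        """Descriptor matrix as a DataFrame indexed by compound id."""
        cols = list(columns) if columns is not None else list(self.descriptor_names)
        rows, index = [], []
        for rec, lab in zip(self.records, self.role_labels):
            if role is not None and lab != role:
                continue
            rows.append([rec.descriptors[c] for c in cols])
            index.append(rec.id)
        return pd.DataFrame(rows, index=index, columns=cols, dtype=float)

    def y(self, role: str | None = None) -> pd.Series:
        """Observed activities (pIC50) indexed by compound id."""
        vals, index = [], []
        for rec, lab in zip(self.records, self.role_labels):
            if role is not None and lab != role:
                continue
            vals.append(np.nan if rec.pic50 is None else rec.pic50)
            index.append(rec.id)
        return pd.Series(vals, index=index, dtype=float, name="pIC50")

    def with_descriptors(self, names: list[str]) -> "Dataset":
        """Same records restricted to the given descriptor columns."""
        unknown = [n for n in names if n not in self.descriptor_names]
        if unknown:
            raise ValidationError(f"unknown descriptor names {unknown}")
        return Dataset(list(self.records), list(names), list(self.role_labels))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: id, smiles, role, descriptors, pIC50."""
        data = {
            "id": self.ids,
            "smiles": [r.smiles or "" for r in self.records],
            "role": [lab or "" for lab in self.role_labels],
        }
        for name in self.descriptor_names:
            data[name] = [r.descriptors[name] for r in self.records]
        data["pIC50"] = [r.pic50 if r.pic50 is not None else np.nan for r in self.records]
        return pd.DataFrame(data)


_RESERVED_COLUMNS = {"id", "smiles", "role"}


def _parse_cell(raw: str, row_label: str, column: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ParseError(
            f"row {row_label!r}, column {column!r}: cannot parse {raw!r} as a number"
        ) from None
    if not math.isfinite(value):
        raise ParseError(
            f"row {row_label!r}, column {column!r}: non-finite value {raw!r}"
        )
    return value


def read_compound_table(
    path,
    format: str = "csv",
    activity_column: str = "pIC50",
    activity_kind: str = "pic50",
    ic50_unit: str | None = None,
    id_column: str = "id",
) -> Dataset:
    """Read a compound table from CSV or SDF-with-properties.

    Every column that is not the id, smiles, role or activity column is
    treated as a descriptor.  An empty activity cell marks a candidate
    record.  ``activity_kind`` selects how the activity column is read:
    ``"pic50"`` (values used verbatim) or ``"ic50"`` (converted using
    ``ic50_unit``).

    Raises
    ------
    ParseError
        On any non-numeric descriptor or activity cell, naming the cell.
    ValidationError
        On duplicate compound ids.
    """
    if activity_kind not in ("pic50", "ic50"):
        raise ConfigurationError(f"activity_kind must be pic50|ic50, got {activity_kind!r}")
    if activity_kind == "ic50" and ic50_unit is None:
        raise ConfigurationError("ic50_unit is required when activity_kind='ic50'")

    if format == "csv":
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        if id_column not in raw.columns:
            raise ParseError(f"missing id column {id_column!r} in {path}")
        rows = []
        for _, row in raw.iterrows():
            rows.append({c: row[c] for c in raw.columns})
        columns = list(raw.columns)
    elif format == "sdf":
        rows, columns = _read_sdf_rows(path, id_column)
    else:
        raise ConfigurationError(f"unknown table format {format!r}")

    descriptor_names = [
        c
        for c in columns
        if c not in _RESERVED_COLUMNS and c != activity_column and c != id_column
    ]

    records = []
    roles: list[str | None] = []
    have_roles = any(str(row.get("role", "")).strip() for row in rows)
    for row in rows:
        cid = str(row[id_column]).strip()
        desc = {
            name: _parse_cell(row[name], cid, name) for name in descriptor_names
        }
        activity_raw = str(row.get(activity_column, "")).strip()
        kwargs: dict = {}
        if activity_raw != "":
            value = _parse_cell(activity_raw, cid, activity_column)
            if activity_kind == "ic50":
                kwargs = {"ic50": value, "ic50_unit": ic50_unit}
            else:
                kwargs = {"pic50": value}
        smiles = str(row.get("smiles", "")).strip() or None
        records.append(CompoundRecord(cid, desc, smiles=smiles, **kwargs))
        role = str(row.get("role", "")).strip()
        if role and role not in ROLES:
            raise ParseError(f"row {cid!r}, column 'role': unknown role {role!r}")
        roles.append(role or ("candidate" if records[-1].is_candidate else None))

    return Dataset(records, descriptor_names, roles if have_roles else [])


def _read_sdf_rows(path, id_column: str):
    """Rows from an SDF whose property fields carry descriptor values."""
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - rdkit is an extra
        raise ConfigurationError("reading SDF requires rdkit") from exc

    rows = []
    columns: list[str] = [id_column, "smiles"]
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"record {i} in {path}: unreadable molecule block")
        props = dict(mol.GetPropsAsDict(includePrivate=False))
        name = str(props.pop(id_column, None) or (mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"))
        row = {id_column: name, "smiles": Chem.MolToSmiles(mol)}
        for key, value in props.items():
            row[key] = str(value)
            if key not in columns:
                columns.append(key)
        rows.append(row)
    return rows, columns


def write_compound_table(ds: Dataset, path) -> None:
    """Write a dataset as CSV, round-tripping floats via shortest repr."""
    frame = ds.to_frame()
    out = frame.copy()
    for col in ds.descriptor_names + ["pIC50"]:
        out[col] = [
            "" if (isinstance(v, float) and math.isnan(v)) else repr(float(v))
            for v in frame[col]
        ]
    out.to_csv(path, index=False)


def split_dataset(
    ds: Dataset,
    train_fraction: float,
    seed: int,
    require_test: bool = True,
) -> Dataset:
    """Assign train/test roles to all non-candidate records.

    The training size is round-half-up of ``train_fraction * n`` where n is
    the number of records with observed activity.  The partition is a
    deterministic function of ``seed``; candidate records keep their role.
    """
    if not (0 < train_fraction <= 1):
        raise ConfigurationError(f"train_fraction must lie in (0, 1], got {train_fraction}")
    eligible = [i for i, r in enumerate(ds.records) if not r.is_candidate]
    n = len(eligible)
    if n < 2:
        raise ConfigurationError(f"need at least 2 records with activity to split, have {n}")
    n_train = int(math.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n)
    if n_train == n and require_test:
        raise ConfigurationError(
            f"train_fraction {train_fraction} leaves an empty test set "
            f"(n = {n}) but external validation is required"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_pos = {eligible[j] for j in order[:n_train]}
    labels: list[str | None] = []
    for i, rec in enumerate(ds.records):
        if rec.is_candidate:
            labels.append("candidate")
        else:
            labels.append("train" if i in train_pos else "test")
    return Dataset(list(ds.records), list(ds.descriptor_names), labels)
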