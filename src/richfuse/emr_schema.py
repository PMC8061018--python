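"""Schema definition, validation, I/O and numeric encoding of the 29-feature
coded clinical record.

The schema is frozen: 29 integer-coded features in a fixed, documented order
(the order below), each with a contiguous code set ``{0, ..., k}``.  The
benign/malignant diagnosis is the *label*, never an input feature.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "StructuredRecord",
    "ValidationReport",
    "load_schema",
    "schema_names",
    "validate_record",
    "encode_record",
    "encode_cohort",
    "read_cohort_table",
    "write_cohort_table",
    "N_FEATURES",
    "LABELS",
]

N_FEATURES = 29
LABELS = ("benign", "malignant")

# (name, max_code, description) — order is frozen and load-bearing: encoded
# vectors, autoencoder inputs and CSV columns all follow it.
_SCHEMA_ROWS: tuple[tuple[str, int, str], ...] = (
    ("Age", 2, "0: <20, 1: 20-40, 2: >40"),
    ("Gender", 1, "0: Male, 1: Female"),
    ("Disease Course Type", 3, "0: Not mentioned, 1: Chronic, 2: Acute, 3: Hidden"),
    ("Pectoral Muscle Adhesion", 1, "0: No, 1: Yes"),
    ("Personal Tumor History", 1, "0: No, 1: Yes"),
    ("Family Tumor History", 1, "0: No, 1: Yes"),
    ("Prophase Treatment", 1, "0: No, 1: Yes"),
    ("Neoadjuvant Chemotherapy", 1, "0: No, 1: Yes"),
    ("Dimple Sign", 1, "0: No, 1: Yes"),
    ("Orange Peel Appearance", 1, "0: No, 1: Yes"),
    ("Redness and Swelling of Skin", 1, "0: No, 1: Yes"),
    ("Skin Ulcers", 1, "0: No, 1: Yes"),
    ("Tumor", 1, "0: No, 1: Yes"),
    ("Breast Deformation", 1, "0: No, 1: Yes"),
    ("Nipple Change", 2, "0: No change, 1: Nipple erosion, 2: Nipple retraction"),
    ("Nipple Discharge", 1, "0: No, 1: Yes"),
    ("Axillary Lymphadenectasis", 3,
     "0: None, 1: Movable, 2: Lymph node fusion, 3: Parasternal metastasis"),
    ("Swelling of Lymph Nodes", 1, "0: No distant metastasis, 1: Distant metastasis"),
    ("Tumor Position", 4, "0: Outer, 1: Upper, 2: Inner lower, 3: Outer lower, 4: Central zone"),
    ("Tumor Number", 2, "0: Single-unilateral, 1: Multiple-unilateral, 2: Bilateral"),
    ("Tumor Size", 2, "0: <20mm, 1: 20-50mm, 2: >50mm"),
    ("Tumor Texture", 4, "0: Soft, 1: Hard, 2: Hard tough, 3: Tough, 4: Moderate"),
    ("Tumor Border", 2, "0: Clear, 1: Unclear, 2: Invasive"),
    ("Smooth Surface", 1, "0: No, 1: Yes"),
    ("Tumor Morphology", 2, "0: Regular, 1: Moderate, 2: Irregular"),
    ("Activity", 2, "0: Good, 1: Moderate, 2: Bad"),
    ("Capsules", 2, "0: No envelope, 1: Incomplete, 2: Enveloped"),
    ("Tenderness", 2, "0: No, 1: Yes, 2: Periodicity"),
    ("Skin Adhesion", 1, "0: No, 1: Yes"),
)


@dataclasses.dataclass(frozen=True)
class FeatureSpec:
    """One coded clinical feature: a name and a contiguous code set."""

    name: str
    codes: frozenset[int]
    description: str = ""

    @property
    def max_code(self) -> int:
        return max(self.codes)

    def __post_init__(self) -> None:
        k = max(self.codes)
        if self.codes != frozenset(range(k + 1)) or k < 1:
            raise ValueError(
                f"codes of {self.name!r} must be {{0..k}} with k >= 1, got {sorted(self.codes)}"
            )


@dataclasses.dataclass
class StructuredRecord:
    """One patient's coded record: 29 integer codes, a missingness mask and a label.

    ``values`` entries at masked positions are ignored (conventionally 0).
    ``label`` is ``"benign"``, ``"malignant"`` or ``None`` (unlabeled).
    """

    patient_id: str
    values: tuple[int, ...]
    missing_mask: tuple[bool, ...] = dataclasses.field(default=None)  # type: ignore[assignment]
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = tuple(int(v) for v in self.values)
        if self.missing_mask is None:
            self.missing_mask = (False,) * len(self.values)
        self.missing_mask = tuple(bool(m) for m in self.missing_mask)


@dataclasses.dataclass
class ValidationReport:
    ok: bool
    violations: list[str]

    def __bool__(self) -> bool:
        return self.ok


def load_schema() -> tuple[FeatureSpec, ...]:
    """Return the 29 feature specs in the frozen schema order."""
    return tuple(
        FeatureSpec(name=name, codes=frozenset(range(k + 1)), description=desc)
        for name, k, desc in _SCHEMA_ROWS
    )


def schema_names(schema: Sequence[FeatureSpec] | None = None) -> list[str]:
    schema = load_schema() if schema is None else schema
    return [f.name for f in schema]


def validate_record(
    record: StructuredRecord, schema: Sequence[FeatureSpec] | None = None
) -> ValidationReport:
    """Check a record against the schema; violations are data, not exceptions."""
    schema = load_schema() if schema is None else schema
    violations: list[str] = []
    if len(record.values) != len(schema):
        violations.append(
            f"record has {len(record.values)} values, schema requires {len(schema)}"
        )
        return ValidationReport(False, violations)
    if len(record.missing_mask) != len(schema):
        violations.append(
            f"missing_mask has {len(record.missing_mask)} entries, schema requires {len(schema)}"
        )
        return ValidationReport(False, violations)
    if record.label is not None and record.label not in LABELS:
        violations.append(f"label {record.label!r} not in {LABELS}")
    for spec, value, missing in zip(schema, record.values, record.missing_mask):
        if missing:
            continue
        if value not in spec.codes:
            violations.append(
                f"feature {spec.name!r}: value {value} not in allowed set "
                f"{sorted(spec.codes)}"
            )
    return ValidationReport(not violations, violations)


def encode_record(
    record: StructuredRecord, schema: Sequence[FeatureSpec] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max encode a record to a 29-d float vector in [0, 1].

    A non-missing code ``c`` of a feature with max code ``k`` maps to ``c/k``;
    missing entries map to 0.0 (the same convention the denoising corruption
    uses).  Returns ``(vector, missing_mask)``.
    """
    schema = load_schema() if schema is None else schema
    report = validate_record(record, schema)
    if not report.ok:
        raise ValueError("cannot encode invalid record: " + "; ".join(report.violations))
    out = np.zeros(len(schema), dtype=np.float64)
    mask = np.asarray(record.missing_mask, dtype=bool)
    for i, (spec, value) in enumerate(zip(schema, record.values)):
        if not mask[i]:
            out[i] = value / spec.max_code
    return out, mask


def encode_cohort(
    records: Iterable[StructuredRecord], schema: Sequence[FeatureSpec] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode many records; returns (X [n,29], masks [n,29], labels [n] of 0/1/-1)."""
    schema = load_schema() if schema is None else schema
    vecs, masks, labels = [], [], []
    for rec in records:
        v, m = encode_record(rec, schema)
        vecs.append(v)
        masks.append(m)
        labels.append(-1 if rec.label is None else LABELS.index(rec.label))
    return np.array(vecs), np.array(masks), np.array(labels)


def read_cohort_table(path: str | Path) -> list[StructuredRecord]:
    """Read a cohort CSV (patient_id, 29 schema columns, label) into records.

    Blank cells become missing-mask entries.  Unknown columns, duplicate
    patient ids and unparseable codes raise ``ValueError`` naming the spot.
    """
    schema = load_schema()
    names = schema_names(schema)
    df = pd.read_csv(path, dtype={"patient_id": str})
    expected = ["patient_id", *names, "label"]
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValueError(f"unknown column(s) in cohort table: {unknown}")
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table is missing column(s): {missing_cols}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate patient_id(s): {sorted(dup.unique())}")

    records: list[StructuredRecord] = []
    for row_idx, row in df.iterrows():
        values, mask = [], []
        for col in names:
            cell = row[col]
            if pd.isna(cell) or (isinstance(cell, str) and not cell.strip()):
                values.append(0)
                mask.append(True)
                continue
            try:
                code = int(cell)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"row {row_idx}, column {col!r}: unparseable code {cell!r}"
                ) from exc
            values.append(code)
            mask.append(False)
        label_cell = row["label"]
        label = None if pd.isna(label_cell) else str(label_cell)
        if label is not None and label not in LABELS:
            raise ValueError(f"row {row_idx}: unknown label {label!r}")
        records.append(
            StructuredRecord(
                patient_id=str(row["patient_id"]),
                values=tuple(values),
                missing_mask=tuple(mask),
                label=label,
            )
        )
    return records


def write_cohort_table(records: Sequence[StructuredRecord], path: str | Path) -> None:
    """Write records as the cohort CSV dialect read back by :func:`read_cohort_table`."""
    names = schema_names()
    seen: set[str] = set()
    rows = []
    for rec in records:
        if rec.patient_id in seen:
            raise ValueError(f"duplicate patient_id {rec.patient_id!r}")
        seen.add(rec.patient_id)
        row: dict[str, object] = {"patient_id": rec.patient_id}
        for name, value, missing in zip(names, rec.values, rec.missing_mask):
            row[name] = "" if missing else int(value)
        row["label"] = "" if rec.label is None else rec.label
        rows.append(row)
    df = pd.DataFrame(rows, columns=["patient_id", *names, "label"])
    df.to_csv(path, index=False)
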