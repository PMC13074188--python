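"""Study-level data model for diagnostic 2x2 tables.

Each primary study contributes one 2x2 contingency table (TP/FP/FN/TN)
obtained by dichotomising CSF heparin-binding protein at a study-specific
cutoff (ng/mL), plus optional categorical covariates (underlying pathology,
design, assay, reference-standard stringency).  This module owns reading,
validation, continuity correction and the logit-scale transformation that
every downstream model consumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "StudyDataset",
    "TransformedStudy",
    "SchemaError",
    "ValidationError",
    "DegenerateProportionError",
    "read_studies",
    "write_studies",
    "apply_continuity_correction",
    "transform_study",
    "transform_dataset",
]


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class ValidationError(ValueError):
    """A row violates the 2x2-table domain constraints."""


class DegenerateProportionError(ValueError):
    """A margin proportion is 0 or 1 and no continuity correction applied."""


#: canonical column names and accepted aliases (case-insensitive)
_REQUIRED = ("study_id", "tp", "fp", "fn", "tn")
_ALIASES = {
    "study_id": {"study_id", "study", "id", "studyid", "author"},
    "tp": {"tp", "true_positive", "true_positives"},
    "fp": {"fp", "false_positive", "false_positives"},
    "fn": {"fn", "false_negative", "false_negatives"},
    "tn": {"tn", "true_negative", "true_negatives"},
    "cutoff": {"cutoff", "cut_off", "threshold", "cutoff_ng_ml"},
}


@dataclass(frozen=True)
class StudyRecord:
    """One study's 2x2 counts with optional cutoff and covariates.

    Raw counts are integers and never mutated; continuity-corrected counts
    live in ``corrected`` (reals) when a correction has been applied.
    """

    study_id: str
    tp: int
    fp: int
    fn: int
    tn: int
    cutoff: float | None = None
    covariates: Mapping[str, str] = field(default_factory=dict)
    corrected: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(
                    f"study {self.study_id!r}: {name}={v!r} must be a non-negative integer"
                )
        if self.tp + self.fn < 1:
            raise ValidationError(f"study {self.study_id!r}: no diseased subjects (tp+fn=0)")
        if self.fp + self.tn < 1:
            raise ValidationError(f"study {self.study_id!r}: no non-diseased subjects (fp+tn=0)")
        if self.cutoff is not None and not self.cutoff > 0:
            raise ValidationError(f"study {self.study_id!r}: cutoff must be positive")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.n_diseased + self.n_nondiseased

    def effective_counts(self) -> tuple[float, float, float, float]:
        """Counts used by estimators: corrected if present, else raw."""
        if self.corrected is not None:
            return self.corrected
        return (float(self.tp), float(self.fp), float(self.fn), float(self.tn))

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class StudyDataset:
    """Ordered collection of study records with unique ids."""

    records: tuple[StudyRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.study_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate study_id values: {dupes}")

    @property
    def k(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return self.k

    def subset(self, predicate) -> "StudyDataset":
        return StudyDataset(
            records=tuple(r for r in self.records if predicate(r)),
            provenance=self.provenance,
        )

    def with_cutoffs(self) -> "StudyDataset":
        return self.subset(lambda r: r.cutoff is not None)

    def covariate_levels(self, name: str, missing: str = "unreported") -> list[str]:
        return [r.covariates.get(name, missing) for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict = {
                "study_id": r.study_id,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "tn": r.tn,
            }
            if r.cutoff is not None:
                row["cutoff"] = r.cutoff
            row.update(r.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TransformedStudy:
    """Logit-scale summary of one study.

    y1 = logit(sensitivity), y2 = logit(false-positive rate); v1, v2 are the
    delta-method (inverse-cell-count) within-study variances.
    """

    study_id: str
    y1: float
    y2: float
    v1: float
    v2: float
    n_diseased: int
    n_nondiseased: int
    corrected: bool

    def __post_init__(self) -> None:
        if not (self.v1 > 0 and self.v2 > 0):
            raise ValidationError(f"study {self.study_id!r}: non-positive variance")
        if not (math.isfinite(self.y1) and math.isfinite(self.y2)):
            raise DegenerateProportionError(
                f"study {self.study_id!r}: infinite logit; apply a continuity correction"
            )


def _map_columns(columns: Sequence[str], mapping: Mapping[str, str] | None) -> dict[str, str]:
    """Resolve actual column names to canonical names, case-insensitively."""
    lower = {c.lower().strip(): c for c in columns}
    out: dict[str, str] = {}
    explicit = {k: v for k, v in (mapping or {}).items()}
    for canon, aliases in _ALIASES.items():
        if canon in explicit:
            if explicit[canon] not in columns:
                raise SchemaError(f"mapped column {explicit[canon]!r} for {canon!r} not in file")
            out[canon] = explicit[canon]
            continue
        for a in aliases:
            if a in lower:
                out[canon] = lower[a]
                break
    missing = [c for c in _REQUIRED if c not in out]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return out


def read_studies(
    path: str | Path,
    *,
    column_mapping: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    provenance: str | None = None,
) -> StudyDataset:
    """Read a delimited study table (CSV/TSV auto-detected) into a dataset.

    Columns beyond study_id/tp/fp/fn/tn/cutoff are kept as categorical
    covariates.  Count columns must be integral; cutoffs positive reals.
    """
    path = Path(path)
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    cols = _map_columns(list(df.columns), column_mapping)
    known = set(cols.values())
    covariate_cols = [c for c in df.columns if c not in known]

    records = []
    for idx, row in df.iterrows():
        sid = str(row[cols["study_id"]]).strip()
        counts = {}
        for name in ("tp", "fp", "fn", "tn"):
            raw = row[cols[name]]
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(f"row {idx} ({sid}): {name}={raw!r} is not a number")
            if not float(val).is_integer():
                raise ValidationError(f"row {idx} ({sid}): {name}={raw!r} is not an integer")
            counts[name] = int(val)
        cutoff = None
        if "cutoff" in cols:
            raw = row[cols["cutoff"]]
            if raw is not None and str(raw).strip() not in ("", "nan", "NA", "None"):
                cutoff = float(raw)
        covs = {
            c: str(row[c]).strip()
            for c in covariate_cols
            if row[c] is not None and str(row[c]).strip() not in ("", "nan")
        }
        records.append(StudyRecord(study_id=sid, cutoff=cutoff, covariates=covs, **counts))
    return StudyDataset(
        records=tuple(records),
        provenance=provenance if provenance is not None else str(path),
    )


def write_studies(dataset: StudyDataset, path: str | Path, *, sidecar_json: bool = True) -> None:
    """Write the dataset back to CSV, with a JSON provenance echo alongside."""
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    if sidecar_json:
        payload = {
            "provenance": dataset.provenance,
            "k": dataset.k,
            "records": [
                {
                    "study_id": r.study_id,
                    "tp": r.tp,
                    "fp": r.fp,
                    "fn": r.fn,
                    "tn": r.tn,
                    "cutoff": r.cutoff,
                    "covariates": dict(r.covariates),
                }
                for r in dataset.records
            ],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(payload, indent=2))


def apply_continuity_correction(
    dataset: StudyDataset,
    value: float = 0.5,
    mode: str = "any-zero-all-cells",
) -> StudyDataset:
    """Continuity-correct zero cells so logits and variances stay finite.

    Modes:
      any-zero-all-cells (default) -- studies containing at least one zero
        cell get ``value`` added to all four cells (the mainstream DTA
        convention); others are untouched.
      only-zero-cells -- add ``value`` only to the zero cells themselves.
      always -- add ``value`` to all four cells of every study.
    """
    if not value > 0:
        raise ValueError("correction value must be positive")
    if mode not in ("any-zero-all-cells", "only-zero-cells", "always"):
        raise ValueError(f"unknown correction mode {mode!r}")

    out = []
    for r in dataset.records:
        cells = (r.tp, r.fp, r.fn, r.tn)
        if mode == "always":
            corr = tuple(c + value for c in cells)
        elif mode == "any-zero-all-cells":
            corr = tuple(c + value for c in cells) if r.has_zero_cell else None
        else:  # only-zero-cells
            corr = tuple(c + value if c == 0 else float(c) for c in cells) if r.has_zero_cell else None
        out.append(replace(r, corrected=corr) if corr is not None else r)
    return StudyDataset(records=tuple(out), provenance=dataset.provenance)


def transform_study(record: StudyRecord) -> TransformedStudy:
    """Logit-transform one study's (corrected) proportions.

    y1 = logit(tp/(tp+fn)), y2 = logit(fp/(fp+tn)); v1 = 1/tp + 1/fn,
    v2 = 1/fp + 1/tn on the effective (possibly corrected) counts.
    """
    tp, fp, fn, tn = record.effective_counts()
    if min(tp, fp, fn, tn) <= 0:
        raise DegenerateProportionError(
            f"study {record.study_id!r}: zero effective cell; enable continuity correction"
        )
    y1 = math.log(tp / fn)
    y2 = math.log(fp / tn)
    v1 = 1.0 / tp + 1.0 / fn
    v2 = 1.0 / fp + 1.0 / tn
    return TransformedStudy(
        study_id=record.study_id,
        y1=y1,
        y2=y2,
        v1=v1,
        v2=v2,
        n_diseased=record.n_diseased,
        n_nondiseased=record.n_nondiseased,
        corrected=record.corrected is not None,
    )


def transform_dataset(
    dataset: StudyDataset,
    *,
    correction: float = 0.5,
    mode: str = "any-zero-all-cells",
) -> list[TransformedStudy]:
    """Continuity-correct then logit-transform every study."""
    corrected = apply_continuity_correction(dataset, value=correction, mode=mode)
    return [transform_study(r) for r in corrected.records]
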