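"""Cohort data model, CSV I/O, variable coding and design matrices.

The cohort is a table of post-AMI patients: coded clinical covariates, a
log10 Nt-proBNP concentration, spike-in-normalised miRNA expression levels
(log2 by default), and the wall motion index score (WMIS, mean of per-segment
contractility scores in [0, 4]) at discharge and at follow-up.  The binary
``impaired`` label (follow-up WMIS strictly above the dichotomisation
threshold, default 1.2 ~ ejection fraction 40%) is always *derived*, never
trusted from disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CodingError, ConfigError, SchemaError, ValidationError

#: Covariates of the clinical reference model (model 1/3): age, sex (female=1,
#: male reference), risk factors, infarct type (STEMI=1) and territory
#: (anterior=1), plus log10 Nt-proBNP.
MODEL1_BASE_VARS: tuple[str, ...] = (
    "age",
    "sex",
    "smoker",
    "diabetes",
    "hypertension",
    "hypercholesterolaemia",
    "prior_mi",
    "stemi",
    "anterior",
    "ntprobnp",
)

#: The four circulating miRNAs of the panel.
DEFAULT_MARKERS: tuple[str, ...] = ("mir_16", "mir_27a", "mir_101", "mir_150")

BINARY_FIELDS: tuple[str, ...] = (
    "smoker",
    "family_history",
    "diabetes",
    "hypertension",
    "hypercholesterolaemia",
    "prior_mi",
    "stemi",
    "anterior",
)

#: Canonical CSV column order (markers are inserted before the WMIS columns).
_FIXED_HEAD = (
    "patient_id",
    "age",
    "sex",
    "smoker",
    "family_history",
    "diabetes",
    "hypertension",
    "hypercholesterolaemia",
    "prior_mi",
    "stemi",
    "anterior",
    "ntprobnp_log10",
)
_FIXED_TAIL = ("wmis_discharge", "wmis_followup")

DEFAULT_THRESHOLD = 1.2


@dataclass(frozen=True)
class PatientRecord:
    """One patient: coded covariates, biomarkers, outcomes.

    ``ntprobnp`` is the log10 plasma concentration; ``mir_levels`` maps
    miRNA name to its (log2 by default) spike-in-normalised expression.
    ``impaired`` is 1 exactly when ``wmis_followup`` exceeds the
    dichotomisation threshold used to build the record.
    """

    patient_id: str
    age: int
    sex: str  # {male, female}
    smoker: int
    family_history: int
    diabetes: int
    hypertension: int
    hypercholesterolaemia: int
    prior_mi: int
    stemi: int
    anterior: int
    ntprobnp: float
    mir_levels: dict[str, float]
    wmis_discharge: float
    wmis_followup: float
    impaired: int

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise CodingError(f"patient {self.patient_id}: sex must be male/female, got {self.sex!r}")
        for name in BINARY_FIELDS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise CodingError(f"patient {self.patient_id}: {name} must be 0 or 1, got {v!r}")
        for name in ("wmis_discharge", "wmis_followup"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 4.0):
                raise ValidationError(f"patient {self.patient_id}: {name}={v!r} outside [0, 4]")
        for key, v in self.mir_levels.items():
            if not np.isfinite(v):
                raise ValidationError(f"patient {self.patient_id}: non-finite level for {key}")
        if not np.isfinite(self.ntprobnp):
            raise ValidationError(f"patient {self.patient_id}: non-finite ntprobnp")


@dataclass
class Cohort:
    """A non-empty sequence of :class:`PatientRecord` sharing one marker panel."""

    patients: list[PatientRecord]
    marker_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.patients:
            raise ValidationError("cohort is empty")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient_id values")
        for p in self.patients:
            if list(p.mir_levels) != list(self.marker_names):
                raise ValidationError(
                    f"patient {p.patient_id}: marker names {list(p.mir_levels)} "
                    f"!= cohort panel {self.marker_names}"
                )

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def n(self) -> int:
        return len(self.patients)

    def columns(self) -> list[str]:
        return list(_FIXED_HEAD) + list(self.marker_names) + list(_FIXED_TAIL)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame in canonical column order (plus ``impaired``)."""
        rows = []
        for p in self.patients:
            row = {
                "patient_id": p.patient_id,
                "age": p.age,
                "sex": p.sex,
                "smoker": p.smoker,
                "family_history": p.family_history,
                "diabetes": p.diabetes,
                "hypertension": p.hypertension,
                "hypercholesterolaemia": p.hypercholesterolaemia,
                "prior_mi": p.prior_mi,
                "stemi": p.stemi,
                "anterior": p.anterior,
                "ntprobnp_log10": p.ntprobnp,
            }
            row.update({m: p.mir_levels[m] for m in self.marker_names})
            row["wmis_discharge"] = p.wmis_discharge
            row["wmis_followup"] = p.wmis_followup
            row["impaired"] = p.impaired
            rows.append(row)
        return pd.DataFrame(rows, columns=self.columns() + ["impaired"])

    def relabel(self, threshold: float) -> "Cohort":
        """Return a cohort with ``impaired`` recomputed at ``threshold``."""
        pts = [
            replace(p, impaired=int(p.wmis_followup > threshold)) for p in self.patients
        ]
        meta = dict(self.metadata)
        meta["threshold"] = threshold
        return Cohort(pts, list(self.marker_names), meta)


def _parse_float(value, col: str, row: int) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        raise ValidationError(f"row {row}: missing value in column {col!r} (no imputation)")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: non-numeric value {value!r} in column {col!r}") from None


def _parse_binary(value, col: str, row: int) -> int:
    v = _parse_float(value, col, row)
    if v not in (0.0, 1.0):
        raise CodingError(f"row {row}: column {col!r} must be 0/1, got {value!r}")
    return int(v)


def read_cohort(
    path,
    schema: dict[str, str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    marker_names: list[str] | None = None,
) -> Cohort:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path : str or PathLike
        CSV file (comma separator, ``.`` decimal, UTF-8, header required).
    schema : dict, optional
        Map from canonical column name to the column name used in the file.
    threshold : float
        Dichotomisation threshold; ``impaired`` is recomputed as
        ``wmis_followup > threshold`` regardless of any stored label.
    marker_names : list of str, optional
        miRNA columns to load.  By default every non-canonical numeric column
        between the fixed head and tail columns is treated as a marker.
    """
    schema = schema or {}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    def col(name: str) -> str:
        return schema.get(name, name)

    needed = list(_FIXED_HEAD) + list(_FIXED_TAIL)
    for name in needed:
        if col(name) not in df.columns:
            raise SchemaError(f"missing required column {col(name)!r}")
    if marker_names is None:
        known = {col(c) for c in needed} | {"impaired"}
        marker_names = [c for c in df.columns if c not in known]
    else:
        for m in marker_names:
            if col(m) not in df.columns:
                raise SchemaError(f"missing marker column {col(m)!r}")
    if not marker_names:
        raise SchemaError("no marker columns found")

    patients = []
    for i, rec in enumerate(df.to_dict("records")):
        sex = rec[col("sex")].strip().lower()
        patients.append(
            PatientRecord(
                patient_id=str(rec[col("patient_id")]),
                age=int(round(_parse_float(rec[col("age")], "age", i))),
                sex=sex,
                smoker=_parse_binary(rec[col("smoker")], "smoker", i),
                family_history=_parse_binary(rec[col("family_history")], "family_history", i),
                diabetes=_parse_binary(rec[col("diabetes")], "diabetes", i),
                hypertension=_parse_binary(rec[col("hypertension")], "hypertension", i),
                hypercholesterolaemia=_parse_binary(
                    rec[col("hypercholesterolaemia")], "hypercholesterolaemia", i
                ),
                prior_mi=_parse_binary(rec[col("prior_mi")], "prior_mi", i),
                stemi=_parse_binary(rec[col("stemi")], "stemi", i),
                anterior=_parse_binary(rec[col("anterior")], "anterior", i),
                ntprobnp=_parse_float(rec[col("ntprobnp_log10")], "ntprobnp_log10", i),
                mir_levels={m: _parse_float(rec[col(m)], m, i) for m in marker_names},
                wmis_discharge=_parse_float(rec[col("wmis_discharge")], "wmis_discharge", i),
                wmis_followup=_parse_float(rec[col("wmis_followup")], "wmis_followup", i),
                impaired=int(_parse_float(rec[col("wmis_followup")], "wmis_followup", i) > threshold),
            )
        )
    return Cohort(patients, list(marker_names), {"source": str(path), "threshold": threshold})


def write_cohort(cohort: Cohort, path) -> str:
    """Write the cohort CSV in canonical column order; round-trips exactly."""
    df = cohort.to_frame().drop(columns=["impaired"])
    df.to_csv(path, index=False)
    return str(path)


def design_matrix(
    cohort: Cohort,
    base_vars: list[str] | tuple[str, ...] = MODEL1_BASE_VARS,
    marker_subset: list[str] | tuple[str, ...] = (),
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Build the regression design matrix and the two outcome vectors.

    Returns ``(X, wmis, impaired)`` where ``X`` has an intercept column
    followed by the requested base covariates (sex coded female=1, male
    reference) and marker columns, ``wmis`` is the continuous follow-up score
    and ``impaired`` the binary label stored on the records.
    """
    df = cohort.to_frame()
    cols = {"intercept": np.ones(len(df))}
    for v in base_vars:
        if v == "sex":
            cols["sex_female"] = (df["sex"] == "female").astype(float).to_numpy()
        elif v == "ntprobnp":
            cols["ntprobnp"] = df["ntprobnp_log10"].astype(float).to_numpy()
        elif v in df.columns and v not in cohort.marker_names:
            cols[v] = df[v].astype(float).to_numpy()
        else:
            raise ConfigError(f"unknown base variable {v!r}")
    for m in marker_subset:
        if m not in cohort.marker_names:
            raise ConfigError(f"unknown marker {m!r}; panel is {cohort.marker_names}")
        cols[m] = df[m].astype(float).to_numpy()
    X = pd.DataFrame(cols)
    wmis = df["wmis_followup"].astype(float).to_numpy()
    impaired = df["impaired"].astype(int).to_numpy()
    return X, wmis, impaired
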