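"""Reading, writing and organizing expression and clinical data.

The expression substrate is a gene x patient matrix of log-ratio
intensities (two-color microarray convention: values roughly centered
at 0, missing cells allowed).  The clinical table carries one row per
patient with overall-survival follow-up.  Binary died/survived labels
at a fixed horizon (default 12 years) are derived from the follow-up,
and the cohort can be split into a training and a validation half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "OutcomeLabels",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "derive_outcome_labels",
    "split_cohort",
]

#: Tokens accepted as "missing" in expression files (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "nan", "null", "none"})


@dataclass
class ExpressionMatrix:
    """Gene x patient matrix of log-ratio expression values.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and patient
        identifiers as the columns; missing measurements are NaN.
    annotations
        Optional per-gene annotation columns (e.g. a systematic clone
        name), indexed like ``values``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise ValueError(f"duplicate patient identifiers: {dups}")
        if self.annotations is not None and not self.annotations.index.equals(idx):
            raise ValueError("annotation index does not match gene identifiers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]

    def subset_patients(self, patient_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(patient_ids)], self.annotations)

    def __eq__(self, other) -> bool:  # value equality, NaN == NaN
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        same_vals = self.values.shape == other.values.shape and bool(
            self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and np.allclose(
                self.values.to_numpy(float),
                other.values.to_numpy(float),
                equal_nan=True,
            )
        )
        return same_vals


@dataclass
class ClinicalTable:
    """Per-patient clinical follow-up.

    ``data`` is indexed by patient identifier with columns
    ``time_years`` (non-negative float), ``death_event`` (bool) and,
    optionally, ``metastasis_event`` (bool) and ``external_label``
    (a published classifier's good/poor call, consumed as-is).
    """

    data: pd.DataFrame

    REQUIRED = ("time_years", "death_event")
    OPTIONAL = ("metastasis_event", "external_label")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if self.data.index.has_duplicates:
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicate patient identifiers: {dups}")
        times = self.data["time_years"].to_numpy(float)
        if np.any(times < 0):
            bad = list(self.data.index[times < 0])
            raise ValueError(f"negative survival time for patients: {bad}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, patient_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(patient_ids)].copy())


@dataclass
class OutcomeLabels:
    """Binary died/survived status of each patient at a fixed horizon."""

    died: pd.Series  # bool, indexed by patient_id
    horizon: float
    censor_policy: str = "survived"

    @property
    def patient_ids(self) -> list[str]:
        return list(self.died.index)

    @property
    def n_died(self) -> int:
        return int(self.died.sum())

    @property
    def n_survived(self) -> int:
        return int((~self.died).sum())

    def status(self) -> pd.Series:
        """Labels as strings 'died'/'survived'."""
        return self.died.map({True: "died", False: "survived"})


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(path, id_cols: int = 1) -> ExpressionMatrix:
    """Read a tab-delimited gene x patient expression matrix.

    The header row names the patient columns; the first ``id_cols``
    columns are gene identifiers (the first is the primary key, any
    further ones are carried as annotations).  Empty cells and the
    tokens NA/NaN/null are treated as missing.  Duplicated gene or
    patient identifiers, and non-numeric cells, raise ``ValueError``.
    """
    if id_cols < 1:
        raise ValueError("id_cols must be >= 1")
    # pandas silently renames repeated header names, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    patient_header = pd.Index(header[id_cols:])
    if patient_header.has_duplicates:
        dups = sorted(patient_header[patient_header.duplicated()].unique())
        raise ValueError(f"duplicate patient identifiers in header: {dups}")
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if raw.shape[1] <= id_cols:
        raise ValueError(f"no patient columns found in {path} (id_cols={id_cols})")
    gene_index = pd.Index(raw.iloc[:, 0].astype(str), name=raw.columns[0])
    annotations = None
    if id_cols > 1:
        annotations = raw.iloc[:, 1:id_cols].copy()
        annotations.index = gene_index
    body = raw.iloc[:, id_cols:]

    patient_cols = body.columns
    if patient_cols.has_duplicates:
        dups = sorted(patient_cols[patient_cols.duplicated()].unique())
        raise ValueError(f"duplicate patient identifiers in header: {dups}")

    cleaned = body.apply(lambda col: col.str.strip())
    is_missing = cleaned.apply(lambda col: col.str.lower().isin(MISSING_TOKENS))
    numeric = cleaned.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~is_missing
    if bad.to_numpy().any():
        gi, pj = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {cleaned.iat[gi, pj]!r} at gene "
            f"{gene_index[gi]!r}, patient {patient_cols[pj]!r}"
        )
    numeric.index = gene_index
    return ExpressionMatrix(numeric.astype(float), annotations)


def write_expression_matrix(expr: ExpressionMatrix, path, float_format: str = "%.6g") -> None:
    """Write an expression matrix to tab-delimited text (missing -> empty)."""
    out = expr.values.copy()
    if expr.annotations is not None:
        out = pd.concat([expr.annotations, out], axis=1)
    out.to_csv(path, sep="\t", na_rep="", float_format=float_format,
               index_label=expr.values.index.name or "gene_id")


# ---------------------------------------------------------------------------
# clinical table I/O
# ---------------------------------------------------------------------------

_BOOL_MAP = {
    "1": True, "0": False, "true": True, "false": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _parse_bool(col: pd.Series, name: str) -> pd.Series:
    vals = col.astype(str).str.strip().str.lower()
    unknown = ~vals.isin(_BOOL_MAP)
    if unknown.any():
        raise ValueError(
            f"column {name!r}: cannot interpret {col[unknown].iloc[0]!r} as boolean"
        )
    return vals.map(_BOOL_MAP)


def read_clinical_table(path) -> ClinicalTable:
    """Read a clinical table from CSV (or TSV if the file ends in .tsv).

    Expected columns: ``patient_id,time_years,death_event`` plus the
    optional ``metastasis_event`` and ``external_label``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "patient_id" not in raw.columns:
        raise ValueError("clinical table must have a 'patient_id' column")
    raw = raw.set_index("patient_id")
    data = pd.DataFrame(index=raw.index)
    data["time_years"] = pd.to_numeric(raw["time_years"])
    data["death_event"] = _parse_bool(raw["death_event"], "death_event")
    if "metastasis_event" in raw.columns:
        data["metastasis_event"] = _parse_bool(raw["metastasis_event"], "metastasis_event")
    if "external_label" in raw.columns:
        data["external_label"] = raw["external_label"].replace("", pd.NA)
    return ClinicalTable(data)


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    out = clinical.data.copy()
    for col in ("death_event", "metastasis_event"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep=sep, index_label="patient_id")


# ---------------------------------------------------------------------------
# outcome labels and cohort split
# ---------------------------------------------------------------------------

def derive_outcome_labels(
    clinical: ClinicalTable,
    horizon: float = 12.0,
    censor_policy: str = "survived",
) -> OutcomeLabels:
    """Binarize survival follow-up at ``horizon`` years.

    A patient is labeled *died* iff the death event occurred within the
    horizon.  Deaths after the horizon count as survived at the
    horizon.  Patients censored at or beyond the horizon are survived.
    Patients censored *before* the horizon have unknown status there;
    ``censor_policy`` either labels them ``"survived"`` (default, keeps
    every patient) or ``"exclude"`` (drops them from the labeling).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if censor_policy not in ("survived", "exclude"):
        raise ValueError(f"unknown censor_policy {censor_policy!r}")
    t = clinical.data["time_years"]
    ev = clinical.data["death_event"].astype(bool)
    died = ev & (t <= horizon)
    if censor_policy == "exclude":
        ambiguous = ~ev & (t < horizon)
        died = died[~ambiguous]
    return OutcomeLabels(died=died.astype(bool), horizon=horizon, censor_policy=censor_policy)


def split_cohort(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    train_fraction: float,
    seed: int,
) -> tuple[tuple[ExpressionMatrix, ClinicalTable], tuple[ExpressionMatrix, ClinicalTable]]:
    """Blindly partition patients into training and validation halves.

    The split is uniformly random given ``seed`` and ignores all
    clinical covariates.  Returns ``((expr_train, clin_train),
    (expr_valid, clin_valid))``; the two patient sets are disjoint and
    exhaustive, with the training size the nearest integer to
    ``n * train_fraction``.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    patients = list(expr.patient_ids)
    if set(patients) != set(clinical.patient_ids):
        raise ValueError("expression and clinical patient sets differ")
    n = len(patients)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_ids = [patients[i] for i in sorted(order[:n_train])]
    valid_ids = [patients[i] for i in sorted(order[n_train:])]
    return (
        (expr.subset_patients(train_ids), clinical.subset(train_ids)),
        (expr.subset_patients(valid_ids), clinical.subset(valid_ids)),
    )
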