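"""Per-patient prognosis scores and ROC-based cutoff selection.

A trained signature turns each patient's expression profile into a
single *overall prognosis score*: the sum over poor-prognosis genes
minus the sum over good-prognosis genes, so that higher means worse
predicted outcome.  The classification cutoff is chosen on labeled
(training) patients as the candidate maximizing sensitivity +
specificity — the Youden criterion over the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretize import discretize
from .io import ExpressionMatrix, OutcomeLabels
from .scoring import Signature

__all__ = [
    "PatientScoreTable",
    "CutoffResult",
    "patient_scores",
    "select_cutoff",
    "classify_patients",
]


@dataclass
class PatientScoreTable:
    """Per-patient poor/good sums and the subtractive overall score.

    ``table`` is indexed by patient with columns ``poor_sum``,
    ``good_sum``, ``overall_score`` (== poor_sum - good_sum) and, once
    a cutoff has been applied, ``predicted_class`` in {"poor","good"}.
    """

    table: pd.DataFrame
    score_mode: str = "continuous"

    def __post_init__(self) -> None:
        t = self.table
        if not np.allclose(
            t["overall_score"], t["poor_sum"] - t["good_sum"], atol=1e-9
        ):
            raise ValueError("overall_score must equal poor_sum - good_sum")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def overall(self) -> pd.Series:
        return self.table["overall_score"]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="patient_id")

    @classmethod
    def read(cls, path) -> "PatientScoreTable":
        t = pd.read_csv(path, sep="\t", index_col="patient_id")
        t.index = t.index.astype(str)
        return cls(t)


@dataclass
class CutoffResult:
    """The selected cutoff with its operating point and the full ROC table."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_total: float
    candidates: pd.DataFrame  # columns: cutoff, sensitivity, specificity, youden_total

    def __post_init__(self) -> None:
        best = self.candidates["youden_total"].max()
        if self.youden_total < best - 1e-12:
            raise ValueError("selected cutoff is not the Youden maximum")


def patient_scores(
    expr: ExpressionMatrix,
    sig: Signature,
    mode: str | None = None,
) -> PatientScoreTable:
    """Score every patient of ``expr`` with a trained signature.

    Continuous mode (the default carried by the signature) sums raw
    log-ratio expression over each gene list, with missing values
    contributing 0.  Discrete mode first re-applies the signature's
    frozen thresholds and sums the resulting {-1, 0, +1} levels.  In
    either mode ``overall_score = poor_sum - good_sum``.
    """
    mode = mode or sig.score_mode
    if mode not in ("continuous", "discrete"):
        raise ValueError(f"unknown score mode {mode!r}")
    absent = [g for g in sig.genes if g not in expr.values.index]
    if absent:
        raise KeyError(f"signature genes missing from expression matrix: {absent}")
    sub = expr.subset_patients(expr.patient_ids)
    member = ExpressionMatrix(sub.values.loc[sig.genes])
    if mode == "continuous":
        mat = member.values.fillna(0.0)
    else:
        mat = discretize(member, sig.cis).astype(float)
    poor_sum = mat.loc[sig.poor_genes].sum(axis=0) if sig.poor_genes else pd.Series(0.0, index=mat.columns)
    good_sum = mat.loc[sig.good_genes].sum(axis=0) if sig.good_genes else pd.Series(0.0, index=mat.columns)
    table = pd.DataFrame(
        {
            "poor_sum": poor_sum,
            "good_sum": good_sum,
            "overall_score": poor_sum - good_sum,
        }
    )
    table.index.name = "patient_id"
    return PatientScoreTable(table, score_mode=mode)


def select_cutoff(scores: PatientScoreTable, labels: OutcomeLabels) -> CutoffResult:
    """Choose the score cutoff maximizing sensitivity + specificity.

    Candidate cutoffs are the midpoints between consecutive distinct
    sorted overall scores, bracketed by -inf and +inf sentinels.  At a
    cutoff c, sensitivity is the fraction of died patients with score
    > c and specificity the fraction of survivors with score <= c.
    Ties in the Youden total resolve to the smallest cutoff, which
    favors sensitivity.
    """
    labeled = [p for p in labels.patient_ids if p in scores.table.index]
    if len(labeled) < len(labels.patient_ids):
        absent = sorted(set(labels.patient_ids) - set(scores.table.index))
        raise KeyError(f"labeled patients without scores: {absent[:10]}")
    s = scores.overall.loc[labeled].to_numpy(float)
    died = labels.died.loc[labeled].to_numpy(bool)
    n_pos = int(died.sum())
    n_neg = int((~died).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cutoff selection needs both died and survived patients")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([-np.inf], mids, [np.inf]))
    sens = np.array([(s[died] > c).mean() for c in candidates])
    spec = np.array([(s[~died] <= c).mean() for c in candidates])
    youden = sens + spec
    best = int(np.argmax(youden))  # argmax takes the first = smallest cutoff on ties
    table = pd.DataFrame(
        {
            "cutoff": candidates,
            "sensitivity": sens,
            "specificity": spec,
            "youden_total": youden,
        }
    )
    return CutoffResult(
        cutoff=float(candidates[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        youden_total=float(youden[best]),
        candidates=table,
    )


def classify_patients(scores: PatientScoreTable, cutoff: float) -> pd.Series:
    """Label each patient poor/good prognosis by the score cutoff.

    Strictly above the cutoff is poor prognosis; at or below is good —
    the same convention ``select_cutoff`` uses for specificity, so the
    operating point it reports is exactly reproduced.
    """
    labels = np.where(scores.overall.to_numpy(float) > cutoff, "poor", "good")
    return pd.Series(labels, index=scores.table.index, name="predicted_class")
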