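"""Validation battery for a trained signature.

Covers the classification metrics (accuracy, sensitivity, specificity
and positive predictive value with poor-prognosis/died as the positive
class), two-group Kaplan-Meier estimation with the log-rank test,
ordinary least-squares regression of follow-up time on the prognosis
score, a rank-based (or t-) comparison of survival times between the
predicted groups, and the single-gene mean-cutoff comparator
(classically applied to Aurora kinase A, whose overexpression marks
highly proliferative tumors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix, OutcomeLabels
from .prognosis import PatientScoreTable

__all__ = [
    "ClassificationMetrics",
    "SurvivalComparison",
    "RegressionResult",
    "classification_metrics",
    "compare_survival",
    "score_time_regression",
    "single_gene_classifier",
]


@dataclass
class ClassificationMetrics:
    """Confusion counts and derived rates; poor/died is the positive class.

    A rate whose denominator is empty (e.g. PPV when nobody was
    predicted poor) is reported as NaN — undefined, not zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return _ratio(self.tp + self.tn, self.n)

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def classification_metrics(predicted: pd.Series, labels: OutcomeLabels) -> ClassificationMetrics:
    """Confusion matrix of poor/good predictions against died/survived labels.

    ``predicted`` maps patient -> "poor"/"good".  Only patients present
    in both inputs are counted; an empty intersection is an error.
    """
    common = [p for p in labels.patient_ids if p in predicted.index]
    if not common:
        raise ValueError("no patients shared between predictions and labels")
    pred_poor = predicted.loc[common].astype(str).eq("poor").to_numpy()
    died = labels.died.loc[common].to_numpy(bool)
    return ClassificationMetrics(
        tp=int((pred_poor & died).sum()),
        fp=int((pred_poor & ~died).sum()),
        tn=int((~pred_poor & ~died).sum()),
        fn=int((~pred_poor & died).sum()),
    )


@dataclass
class SurvivalComparison:
    """Kaplan-Meier curves per group plus the between-group tests."""

    km_curves: dict  # group -> DataFrame(time, at_risk, survival)
    logrank_statistic: float
    logrank_p: float
    mean_test: str
    mean_statistic: float
    mean_p: float
    group_sizes: dict = field(default_factory=dict)


def compare_survival(
    groups: pd.Series,
    clinical: ClinicalTable,
    mean_test: str = "mannwhitney",
) -> SurvivalComparison:
    """Compare survival between predicted prognosis groups.

    Right-censored Kaplan-Meier curves are estimated per group
    (event = death), group equality is tested with the two-sided
    log-rank test, and the raw times to death or censure are compared
    with a two-sided Mann-Whitney U test (``mean_test="ttest"``
    switches to Welch's t-test).
    """
    if mean_test not in ("mannwhitney", "ttest"):
        raise ValueError(f"unknown mean_test {mean_test!r}")
    common = [p for p in clinical.patient_ids if p in groups.index]
    if not common:
        raise ValueError("no patients shared between groups and clinical table")
    g = groups.loc[common].astype(str)
    names = sorted(g.unique())
    if len(names) < 2:
        raise ValueError(f"need two non-empty groups, got {names}")
    times = clinical.data.loc[common, "time_years"].to_numpy(float)
    events = clinical.data.loc[common, "death_event"].to_numpy(bool)

    curves = {}
    sizes = {}
    for name in names:
        mask = (g == name).to_numpy()
        sizes[name] = int(mask.sum())
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], event_observed=events[mask], label=name)
        tbl = kmf.event_table
        curves[name] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(float),
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(float),
                "survival": kmf.survival_function_[name].to_numpy(float),
            }
        )

    lr = multivariate_logrank_test(times, g.to_numpy(), events)
    ga, gb = names[0], names[1]
    ta = times[(g == ga).to_numpy()]
    tb = times[(g == gb).to_numpy()]
    if mean_test == "mannwhitney":
        res = stats.mannwhitneyu(ta, tb, alternative="two-sided")
    else:
        res = stats.ttest_ind(ta, tb, equal_var=False)
    return SurvivalComparison(
        km_curves=curves,
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        mean_test=mean_test,
        mean_statistic=float(res.statistic),
        mean_p=float(res.pvalue),
        group_sizes=sizes,
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    r_squared: float
    n: int


def score_time_regression(scores: PatientScoreTable, clinical: ClinicalTable) -> RegressionResult:
    """OLS of time-to-death-or-censure on the overall prognosis score.

    The score is the independent variable; a working signature shows a
    significant negative slope (higher score, shorter follow-up).  The
    zero-slope F-test of the simple regression is reported (identical
    to the squared-t test).
    """
    common = [p for p in clinical.patient_ids if p in scores.table.index]
    if len(common) < 3:
        raise ValueError("regression needs at least 3 patients with scores")
    x = scores.overall.loc[common].to_numpy(float)
    y = clinical.data.loc[common, "time_years"].to_numpy(float)
    if np.allclose(x, x[0]):
        raise ValueError("constant prognosis scores: slope test undefined")
    fit = stats.linregress(x, y)
    df = len(common) - 2
    if fit.stderr == 0:  # exact collinearity
        f_stat, p = math.inf, 0.0
    else:
        t = fit.slope / fit.stderr
        f_stat = t * t
        p = float(stats.f.sf(f_stat, 1, df))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        f_statistic=float(f_stat),
        p_value=p,
        r_squared=float(fit.rvalue**2),
        n=len(common),
    )


def single_gene_classifier(
    expr: ExpressionMatrix,
    gene_id: str,
    orientation: str = "high_is_poor",
) -> pd.Series:
    """Mean-cutoff classifier from a single gene's expression.

    The cutoff is the gene's mean over patients with a measurement.
    With ``high_is_poor`` (the convention for proliferation markers
    such as Aurora kinase A), values strictly above the mean predict
    poor prognosis; ``low_is_poor`` flips the call.  Patients missing
    the measurement fall on the good side of ``high_is_poor`` and the
    poor side of ``low_is_poor`` — i.e. the "not above the cutoff" arm.
    """
    if orientation not in ("high_is_poor", "low_is_poor"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if gene_id not in expr.values.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    vals = expr.values.loc[gene_id]
    if vals.notna().sum() == 0:
        raise ValueError(f"gene {gene_id!r} has no non-missing values")
    cutoff = float(vals.mean(skipna=True))
    above = vals.to_numpy(float) > cutoff  # NaN compares False
    if orientation == "high_is_poor":
        lab = np.where(above, "poor", "good")
    else:
        lab = np.where(above, "good", "poor")
    return pd.Series(lab, index=expr.values.columns, name="predicted_class")
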