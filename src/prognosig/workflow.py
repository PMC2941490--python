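"""End-to-end train / apply / evaluate convenience wrappers.

These compose the module-level operations in the order a user runs
them: discretize the training cohort, score and rank genes, assemble
the signature, score the training patients and freeze the
Youden-optimal cutoff inside the signature; later, apply the frozen
signature to new patients and evaluate the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .discretize import compute_gene_ci, discretize
from .evaluation import (
    ClassificationMetrics,
    RegressionResult,
    SurvivalComparison,
    classification_metrics,
    compare_survival,
    score_time_regression,
)
from .io import ClinicalTable, ExpressionMatrix, OutcomeLabels, derive_outcome_labels
from .prognosis import (
    CutoffResult,
    PatientScoreTable,
    classify_patients,
    patient_scores,
    select_cutoff,
)
from .scoring import GeneScoreTable, Signature, build_signature, score_genes

__all__ = ["TrainResult", "EvaluationReport", "train_signature", "apply_signature", "evaluate_predictions"]


@dataclass
class TrainResult:
    signature: Signature            # carries the selected cutoff
    gene_scores: GeneScoreTable
    train_scores: PatientScoreTable
    cutoff_result: CutoffResult
    labels: OutcomeLabels


def train_signature(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    k_poor: int = 10,
    k_good: int = 10,
    horizon: float = 12.0,
    censor_policy: str = "survived",
    confidence: float = 0.95,
    ci_method: str = "normal",
    score_mode: str = "continuous",
) -> TrainResult:
    """Full training pass on one cohort.

    The per-gene thresholds are computed on this cohort and frozen
    into the returned signature, as is the cutoff selected on this
    cohort's scores — nothing about validation patients enters here.
    """
    labels = derive_outcome_labels(clinical, horizon=horizon, censor_policy=censor_policy)
    cis = compute_gene_ci(expr, confidence=confidence, method=ci_method)
    disc = discretize(expr, cis)
    gene_scores = score_genes(disc, labels)
    sig = build_signature(
        gene_scores,
        cis,
        k_poor=k_poor,
        k_good=k_good,
        score_mode=score_mode,
        provenance={
            "n_training_patients": expr.n_patients,
            "n_genes_scored": expr.n_genes,
            "horizon_years": horizon,
            "censor_policy": censor_policy,
            "ci_method": ci_method,
            "confidence": confidence,
        },
    )
    train_scores = patient_scores(expr, sig)
    cut = select_cutoff(train_scores, labels)
    sig.cutoff = cut.cutoff
    return TrainResult(sig, gene_scores, train_scores, cut, labels)


def apply_signature(
    expr: ExpressionMatrix,
    sig: Signature,
    cutoff: float | None = None,
) -> PatientScoreTable:
    """Score and classify new patients with a frozen signature."""
    scores = patient_scores(expr, sig)
    cut = sig.cutoff if cutoff is None else cutoff
    if cut is not None:
        scores.table["predicted_class"] = classify_patients(scores, cut)
    return scores


@dataclass
class EvaluationReport:
    metrics: ClassificationMetrics
    survival: SurvivalComparison
    regression: RegressionResult

    def as_dict(self) -> dict:
        return {
            "classification": self.metrics.as_dict(),
            "logrank": {
                "statistic": self.survival.logrank_statistic,
                "p_value": self.survival.logrank_p,
                "group_sizes": self.survival.group_sizes,
            },
            "mean_survival_test": {
                "test": self.survival.mean_test,
                "statistic": self.survival.mean_statistic,
                "p_value": self.survival.mean_p,
            },
            "score_time_regression": {
                "slope": self.regression.slope,
                "intercept": self.regression.intercept,
                "f_statistic": self.regression.f_statistic,
                "p_value": self.regression.p_value,
                "r_squared": self.regression.r_squared,
                "n": self.regression.n,
            },
        }


def evaluate_predictions(
    scores: PatientScoreTable,
    clinical: ClinicalTable,
    horizon: float = 12.0,
    censor_policy: str = "survived",
    mean_test: str = "mannwhitney",
) -> EvaluationReport:
    """The full validation battery on classified patient scores."""
    if "predicted_class" not in scores.table.columns:
        raise ValueError("scores carry no predicted_class; apply a cutoff first")
    labels = derive_outcome_labels(clinical, horizon=horizon, censor_policy=censor_policy)
    predicted = scores.table["predicted_class"]
    metrics = classification_metrics(predicted, labels)
    survival = compare_survival(predicted, clinical, mean_test=mean_test)
    regression = score_time_regression(scores, clinical)
    return EvaluationReport(metrics, survival, regression)
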