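"""Ternary coarse-graining of expression by per-gene confidence interval.

Each gene's measurements across a reference cohort define a 95%
confidence interval of the *mean* log-ratio (mean +/- q * s / sqrt(n)).
A patient's value is then called ``high`` (+1) if it exceeds the upper
bound, ``low`` (-1) if it falls below the lower bound, and ``average``
(0) otherwise.  Because the interval is a standard-error band, it
tightens as the cohort grows and an increasing share of patients is
called high or low — the discretization deliberately flags even modest
departures from the cohort mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = ["GeneCISet", "compute_gene_ci", "discretize",
           "write_gene_ci", "read_gene_ci"]

LEVEL_LOW, LEVEL_AVERAGE, LEVEL_HIGH = -1, 0, 1


@dataclass
class GeneCISet:
    """Per-gene mean and confidence bounds: the frozen discretization thresholds.

    ``table`` is indexed by gene with columns ``mean``, ``ci_upper``,
    ``ci_lower`` and ``n_used`` (number of non-missing measurements).
    """

    table: pd.DataFrame
    confidence: float = 0.95
    method: str = "normal"
    cohort: str = ""

    def __post_init__(self) -> None:
        for col in ("mean", "ci_upper", "ci_lower"):
            if col not in self.table.columns:
                raise ValueError(f"CI table missing column {col!r}")
        bad = (self.table["ci_lower"] > self.table["mean"] + 1e-12) | (
            self.table["ci_upper"] < self.table["mean"] - 1e-12
        )
        if bad.any():
            raise ValueError(
                f"CI bounds do not bracket the mean for genes: {list(self.table.index[bad])[:5]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, gene_ids) -> "GeneCISet":
        missing = [g for g in gene_ids if g not in self.table.index]
        if missing:
            raise KeyError(f"genes absent from CI set: {missing}")
        return GeneCISet(self.table.loc[list(gene_ids)].copy(),
                         self.confidence, self.method, self.cohort)


def compute_gene_ci(
    expr: ExpressionMatrix,
    confidence: float = 0.95,
    method: str = "normal",
    cohort: str = "",
) -> GeneCISet:
    """Confidence interval of the mean expression of every gene.

    The half-width is ``q * s / sqrt(n)`` with ``s`` the sample standard
    deviation (n-1 denominator) over non-missing values and ``q`` the
    two-sided normal quantile (1.96 at 95%) or, with ``method="t"``,
    the Student-t quantile with n-1 degrees of freedom.  Genes with a
    single measurement or zero variance get the degenerate interval
    ``[mean, mean]``; a gene with no measurements at all is an error.
    """
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    if method not in ("normal", "t"):
        raise ValueError(f"unknown CI method {method!r}")
    vals = expr.values
    n = vals.notna().sum(axis=1).astype(int)
    if (n == 0).any():
        empty = list(vals.index[n == 0])
        raise ValueError(f"genes with zero non-missing values: {empty[:10]}")
    mean = vals.mean(axis=1, skipna=True)
    sd = vals.std(axis=1, ddof=1, skipna=True).fillna(0.0)
    alpha = 1.0 - confidence
    if method == "normal":
        q = pd.Series(stats.norm.ppf(1.0 - alpha / 2.0), index=vals.index)
    else:
        df = (n - 1).clip(lower=1)
        q = pd.Series(stats.t.ppf(1.0 - alpha / 2.0, df=df), index=vals.index)
    half = (q * sd / np.sqrt(n)).where((n > 1) & (sd > 0), 0.0)
    table = pd.DataFrame(
        {
            "mean": mean,
            "ci_upper": mean + half,
            "ci_lower": mean - half,
            "n_used": n,
        }
    )
    return GeneCISet(table, confidence=confidence, method=method, cohort=cohort)


def discretize(expr: ExpressionMatrix, cis: GeneCISet) -> pd.DataFrame:
    """Map every expression value to a level in {-1, 0, +1}.

    Strict inequalities: a value must exceed ``ci_upper`` to be high and
    fall below ``ci_lower`` to be low; values on a boundary, inside the
    interval, or missing are the neutral level 0.  The CI set may come
    from a different cohort than ``expr`` (frozen thresholds); every
    gene of ``expr`` must be present in it.
    """
    missing = [g for g in expr.gene_ids if g not in cis.table.index]
    if missing:
        raise KeyError(f"genes absent from CI set: {missing[:10]}")
    sub = cis.table.loc[expr.values.index]
    vals = expr.values.to_numpy(float)
    upper = sub["ci_upper"].to_numpy(float)[:, None]
    lower = sub["ci_lower"].to_numpy(float)[:, None]
    levels = np.zeros(vals.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        levels[vals > upper] = LEVEL_HIGH
        levels[vals < lower] = LEVEL_LOW
    return pd.DataFrame(levels, index=expr.values.index, columns=expr.values.columns)


# ---------------------------------------------------------------------------
# serialization — a TSV with one row per gene, mirroring the signature's
# published threshold table (identifier, optional systematic name,
# average, upper, lower)
# ---------------------------------------------------------------------------

def write_gene_ci(cis: GeneCISet, path, annotations: pd.Series | None = None) -> None:
    out = pd.DataFrame(index=cis.table.index)
    out["systematic_name"] = (
        annotations.reindex(cis.table.index).fillna("") if annotations is not None else ""
    )
    out["average"] = cis.table["mean"]
    out["upper"] = cis.table["ci_upper"]
    out["lower"] = cis.table["ci_lower"]
    if "n_used" in cis.table.columns:
        out["n_used"] = cis.table["n_used"]
    out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_gene_ci(path, confidence: float = 0.95) -> GeneCISet:
    raw = pd.read_csv(path, sep="\t", index_col="gene_id")
    table = pd.DataFrame(
        {
            "mean": raw["average"].astype(float),
            "ci_upper": raw["upper"].astype(float),
            "ci_lower": raw["lower"].astype(float),
        },
        index=raw.index.astype(str),
    )
    if "n_used" in raw.columns:
        table["n_used"] = raw["n_used"].astype(int)
    return GeneCISet(table, confidence=confidence)
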