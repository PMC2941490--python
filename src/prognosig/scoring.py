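"""Univariate outcome-concordance scoring and signature assembly.

Every gene receives an integer *poor-prognosis score* tallied over the
labeled patients of the training cohort: +1 for each patient with high
expression who died or low expression who survived, -1 for each with
low expression who died or high expression who survived; the neutral
(average/missing) level never moves the score.  The *good-prognosis
score* applies the mirrored rules and therefore equals the negated
poor score exactly.  Genes are ranked by each score and the top-k of
each orientation, together with their frozen discretization
thresholds, form the signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .discretize import GeneCISet
from .io import OutcomeLabels

__all__ = [
    "GeneScoreTable",
    "Signature",
    "score_genes",
    "rank_genes",
    "build_signature",
    "random_signature",
    "write_signature",
    "read_signature",
    "write_gene_scores",
]


@dataclass
class GeneScoreTable:
    """Per-gene concordance scores and ranks.

    ``table`` is indexed by gene with columns ``poor_score``,
    ``good_score`` (== -poor_score), ``n_informative`` (labeled
    patients with a non-neutral level), ``poor_rank`` and ``good_rank``
    (1 = best of that orientation; ties broken by gene identifier).
    """

    table: pd.DataFrame
    n_labeled: int = 0

    def __post_init__(self) -> None:
        t = self.table
        if not (t["good_score"] == -t["poor_score"]).all():
            raise ValueError("good_score must equal -poor_score for every gene")
        if (t["poor_score"].abs() > t["n_informative"]).any():
            raise ValueError("|score| cannot exceed the number of informative patients")


def score_genes(disc: pd.DataFrame, labels: OutcomeLabels) -> GeneScoreTable:
    """Score every gene's concordance between levels and outcomes.

    ``disc`` is a discretized gene x patient matrix of levels in
    {-1, 0, +1}.  Both orientations are returned in one table; the
    mirror identity good_score == -poor_score makes a second pass
    redundant.  Patients without a label are skipped.
    """
    labeled = [p for p in labels.patient_ids if p in disc.columns]
    if len(labeled) < len(labels.patient_ids):
        absent = sorted(set(labels.patient_ids) - set(disc.columns))
        raise KeyError(f"labeled patients absent from discretized matrix: {absent[:10]}")
    if not labeled:
        raise ValueError("no labeled patients to score against")
    levels = disc.loc[:, labeled].to_numpy()
    # died -> +1, survived -> -1: the poor score is then a plain inner product
    outcome_sign = np.where(labels.died.loc[labeled].to_numpy(bool), 1, -1)
    poor = levels @ outcome_sign
    n_informative = (levels != 0).sum(axis=1)
    table = pd.DataFrame(
        {
            "poor_score": poor.astype(int),
            "good_score": (-poor).astype(int),
            "n_informative": n_informative.astype(int),
        },
        index=disc.index,
    )
    for orient in ("poor", "good"):
        order = _ordered_index(table, orient)
        table.loc[order, f"{orient}_rank"] = np.arange(1, len(order) + 1)
    table["poor_rank"] = table["poor_rank"].astype(int)
    table["good_rank"] = table["good_rank"].astype(int)
    return GeneScoreTable(table, n_labeled=len(labeled))


def _ordered_index(table: pd.DataFrame, orientation: str) -> pd.Index:
    col = f"{orientation}_score"
    tmp = table[[col]].copy()
    tmp["_gid"] = tmp.index.astype(str)
    return tmp.sort_values([col, "_gid"], ascending=[False, True]).index


def rank_genes(scores: GeneScoreTable, orientation: str) -> list[str]:
    """Genes ordered best-first for one orientation.

    Descending score; ties broken by ascending gene identifier so the
    ranking is deterministic.
    """
    if orientation not in ("poor", "good"):
        raise ValueError(f"orientation must be 'poor' or 'good', got {orientation!r}")
    if len(scores.table) == 0:
        raise ValueError("empty score table")
    return list(_ordered_index(scores.table, orientation))


@dataclass
class Signature:
    """A trained predictor: ordered gene lists + frozen thresholds + cutoff.

    ``score_mode`` selects how patient scores are formed downstream:
    ``"continuous"`` sums raw expression of the member genes,
    ``"discrete"`` sums their {-1, 0, +1} levels after re-applying the
    frozen thresholds.  ``cutoff`` (once selected on training data)
    separates poor from good prognosis: overall score > cutoff -> poor.
    """

    poor_genes: list[str]
    good_genes: list[str]
    cis: GeneCISet
    score_mode: str = "continuous"
    cutoff: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.poor_genes) & set(self.good_genes)
        if overlap:
            raise ValueError(f"genes in both lists: {sorted(overlap)}")
        if self.score_mode not in ("continuous", "discrete"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        members = self.poor_genes + self.good_genes
        absent = [g for g in members if g not in self.cis.table.index]
        if absent:
            raise ValueError(f"signature genes missing from frozen CI set: {absent}")

    @property
    def genes(self) -> list[str]:
        return self.poor_genes + self.good_genes

    @property
    def size(self) -> int:
        return len(self.poor_genes) + len(self.good_genes)


def build_signature(
    scores: GeneScoreTable,
    cis: GeneCISet,
    k_poor: int,
    k_good: int,
    score_mode: str = "continuous",
    provenance: dict | None = None,
) -> Signature:
    """Assemble the top-``k_poor`` + top-``k_good`` gene signature.

    The two rankings are reversals of each other, so with nondegenerate
    scores the lists cannot collide; if a gene nevertheless tops both
    (tiny all-zero inputs), it stays in the orientation where its score
    is at least as large and the other list takes its next candidate.
    """
    if k_poor < 0 or k_good < 0 or k_poor + k_good <= 0:
        raise ValueError("signature sizes must be non-negative with k_poor + k_good > 0")
    if k_poor + k_good > len(scores.table):
        raise ValueError("k_poor + k_good exceeds the number of scored genes")
    poor_ranked = rank_genes(scores, "poor")
    good_ranked = rank_genes(scores, "good")
    poor_sel = poor_ranked[:k_poor]
    good_sel: list[str] = []
    taken = set(poor_sel)
    t = scores.table
    for g in good_ranked:
        if len(good_sel) == k_good:
            break
        if g in taken:
            # contested gene: keep it where its score is strictly higher
            if t.at[g, "good_score"] > t.at[g, "poor_score"]:
                poor_sel.remove(g)
                taken.discard(g)
                for cand in poor_ranked:
                    if cand not in taken and cand not in good_sel and cand != g:
                        poor_sel.append(cand)
                        taken.add(cand)
                        break
            else:
                continue
        good_sel.append(g)
        taken.add(g)
    return Signature(
        poor_genes=poor_sel,
        good_genes=good_sel,
        cis=cis.subset(poor_sel + good_sel),
        score_mode=score_mode,
        provenance=dict(provenance or {}),
    )


def random_signature(
    gene_ids,
    k_poor: int,
    k_good: int,
    seed: int,
    cis: GeneCISet,
    score_mode: str = "continuous",
) -> Signature:
    """Size-matched control signature of uniformly sampled genes.

    Samples ``k_poor + k_good`` distinct genes without replacement and
    assigns the first ``k_poor`` to the poor list — the split is
    arbitrary, as the control is meant to carry no outcome information.
    """
    gene_ids = list(gene_ids)
    if k_poor < 0 or k_good < 0 or k_poor + k_good <= 0:
        raise ValueError("signature sizes must be non-negative with k_poor + k_good > 0")
    if k_poor + k_good > len(gene_ids):
        raise ValueError("not enough genes to sample the requested signature")
    rng = np.random.default_rng(seed)
    chosen = [gene_ids[i] for i in rng.choice(len(gene_ids), size=k_poor + k_good, replace=False)]
    return Signature(
        poor_genes=chosen[:k_poor],
        good_genes=chosen[k_poor:],
        cis=cis.subset(chosen),
        score_mode=score_mode,
        provenance={"kind": "random_control", "seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_gene_scores(scores: GeneScoreTable, path) -> None:
    cols = ["poor_score", "good_score", "n_informative", "poor_rank", "good_rank"]
    scores.table[cols].to_csv(path, sep="\t", index_label="gene_id")


def write_signature(sig: Signature, path) -> None:
    """Serialize a signature to a YAML file (gene lists, thresholds, cutoff)."""
    ci_rows = [
        {
            "gene_id": str(g),
            "mean": float(sig.cis.table.at[g, "mean"]),
            "ci_upper": float(sig.cis.table.at[g, "ci_upper"]),
            "ci_lower": float(sig.cis.table.at[g, "ci_lower"]),
        }
        for g in sig.genes
    ]
    doc = {
        "format": "prognosig-signature-v1",
        "poor_genes": [str(g) for g in sig.poor_genes],
        "good_genes": [str(g) for g in sig.good_genes],
        "score_mode": sig.score_mode,
        "cutoff": None if sig.cutoff is None else float(sig.cutoff),
        "confidence": float(sig.cis.confidence),
        "ci": ci_rows,
        "provenance": sig.provenance,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_signature(path) -> Signature:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("format") != "prognosig-signature-v1":
        raise ValueError(f"{path} is not a prognosig signature file")
    ci_table = pd.DataFrame(doc["ci"]).set_index("gene_id")
    cis = GeneCISet(ci_table, confidence=float(doc.get("confidence", 0.95)))
    return Signature(
        poor_genes=list(doc["poor_genes"]),
        good_genes=list(doc["good_genes"]),
        cis=cis,
        score_mode=doc.get("score_mode", "continuous"),
        cutoff=doc.get("cutoff"),
        provenance=doc.get("provenance") or {},
    )
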