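import numpy as np
import pandas as pd
import pytest

from prognosig import (
    GeneScoreTable,
    OutcomeLabels,
    Signature,
    build_signature,
    random_signature,
    rank_genes,
    read_signature,
    score_genes,
    write_signature,
)
from conftest import random_levels
from oracles import brute_force_gene_scores


def _labels(died: dict) -> OutcomeLabels:
    return OutcomeLabels(died=pd.Series(died), horizon=12.0)


def _dummy_cis(gene_ids) -> "GeneCISet":
    from prognosig import GeneCISet

    n = len(gene_ids)
    return GeneCISet(
        pd.DataFrame(
            {"mean": np.zeros(n), "ci_upper": np.full(n, 0.1), "ci_lower": np.full(n, -0.1)},
            index=pd.Index(list(gene_ids), name="gene_id"),
        )
    )


class TestScoreGenes:
    def test_rule_application_example(self):
        # (high, died) +1; (low, survived) +1; (average, died) 0 -> poor 2
        disc = pd.DataFrame({"P1": [1], "P2": [-1], "P3": [0]}, index=["g"])
        labels = _labels({"P1": True, "P2": False, "P3": True})
        t = score_genes(disc, labels).table
        assert t.at["g", "poor_score"] == 2
        assert t.at["g", "good_score"] == -2
        assert t.at["g", "n_informative"] == 2

    def test_all_average_gene_scores_zero(self):
        disc = pd.DataFrame({"P1": [0], "P2": [0]}, index=["g"])
        t = score_genes(disc, _labels({"P1": True, "P2": False})).table
        assert t.at["g", "poor_score"] == 0
        assert t.at["g", "good_score"] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        disc = random_levels(rng, 50, 20)
        died = pd.Series(rng.random(20) < 0.5, index=disc.columns)
        expected = brute_force_gene_scores(disc, died)
        got = score_genes(disc, OutcomeLabels(died, 12.0)).table
        assert (got["poor_score"] == expected["poor"]).all()
        assert (got["good_score"] == expected["good"]).all()

    def test_antisymmetry_and_outcome_flip(self):
        rng = np.random.default_rng(11)
        disc = random_levels(rng, 30, 15)
        died = pd.Series(rng.random(15) < 0.4, index=disc.columns)
        t = score_genes(disc, OutcomeLabels(died, 12.0)).table
        assert (t["good_score"] == -t["poor_score"]).all()
        flipped = score_genes(disc, OutcomeLabels(~died, 12.0)).table
        assert (flipped["poor_score"] == -t["poor_score"]).all()

    def test_patient_permutation_invariance(self):
        rng = np.random.default_rng(12)
        disc = random_levels(rng, 20, 10)
        died = pd.Series(rng.random(10) < 0.5, index=disc.columns)
        t1 = score_genes(disc, OutcomeLabels(died, 12.0)).table
        perm = list(rng.permutation(disc.columns))
        t2 = score_genes(disc[perm], OutcomeLabels(died.loc[perm], 12.0)).table
        assert (t1["poor_score"] == t2["poor_score"]).all()

    def test_unlabeled_patient_in_matrix_contributes_nothing(self):
        disc = pd.DataFrame({"P1": [1], "P2": [1], "P3": [1]}, index=["g"])
        t = score_genes(disc, _labels({"P1": True, "P2": True})).table
        assert t.at["g", "poor_score"] == 2

    def test_label_without_matrix_column_is_an_error(self):
        disc = pd.DataFrame({"P1": [1]}, index=["g"])
        with pytest.raises(KeyError, match="P9"):
            score_genes(disc, _labels({"P1": True, "P9": False}))

    def test_no_labels_is_an_error(self):
        disc = pd.DataFrame({"P1": [1]}, index=["g"])
        with pytest.raises(ValueError):
            score_genes(disc, OutcomeLabels(pd.Series(dtype=bool), 12.0))

    def test_null_scores_center_at_zero(self):
        """With levels independent of outcomes the score is a lazy random
        walk endpoint: mean within 3 SE of zero."""
        rng = np.random.default_rng(2024)
        n_genes, n_patients = 400, 60
        disc = random_levels(rng, n_genes, n_patients)
        died = pd.Series(rng.random(n_patients) < 0.5, index=disc.columns)
        scores = score_genes(disc, OutcomeLabels(died, 12.0)).table["poor_score"]
        p_noneutral = 2 / 3
        se = np.sqrt(n_patients * p_noneutral / n_genes)
        assert abs(scores.mean()) < 3 * se


class TestRanking:
    def _table(self, poor: dict) -> GeneScoreTable:
        idx = pd.Index(sorted(poor), name="gene_id")
        t = pd.DataFrame(
            {
                "poor_score": [poor[g] for g in idx],
                "good_score": [-poor[g] for g in idx],
                "n_informative": [abs(poor[g]) + 2 for g in idx],
            },
            index=idx,
        )
        t["poor_rank"] = 0
        t["good_rank"] = 0
        return GeneScoreTable(t)

    def test_descending_with_lexicographic_ties(self):
        ranked = rank_genes(self._table({"gA": 5, "gB": 7, "gC": 5}), "poor")
        assert ranked == ["gB", "gA", "gC"]

    def test_deterministic(self):
        t = self._table({"gA": 1, "gB": 1, "gC": 1, "gD": 0})
        assert rank_genes(t, "poor") == rank_genes(t, "poor")

    @pytest.mark.parametrize("seed", range(3))
    def test_good_ranking_reverses_poor_up_to_ties(self, seed):
        rng = np.random.default_rng(seed)
        poor = {f"g{i}": int(s) for i, s in enumerate(rng.integers(-20, 21, 15))}
        # make scores distinct so the reversal is exact
        poor = {g: v * 50 + i for i, (g, v) in enumerate(sorted(poor.items()))}
        t = self._table(poor)
        assert rank_genes(t, "good") == rank_genes(t, "poor")[::-1]

    def test_rank_columns_are_permutations(self):
        rng = np.random.default_rng(5)
        disc = random_levels(rng, 25, 12)
        died = pd.Series(rng.random(12) < 0.5, index=disc.columns)
        t = score_genes(disc, OutcomeLabels(died, 12.0)).table
        for col in ("poor_rank", "good_rank"):
            assert sorted(t[col]) == list(range(1, 26))


class TestBuildSignature:
    def test_toy_selection_matches_hand_enumeration(self):
        # hand-checkable 4-gene table: poor scores 6, 3, -2, -5, so the
        # poor list is [gA, gB] and the good list [gD, gC]
        t = TestRanking()._table({"gA": 6, "gB": 3, "gC": -2, "gD": -5})
        sig = build_signature(t, _dummy_cis(["gA", "gB", "gC", "gD"]), k_poor=2, k_good=2)
        assert sig.poor_genes == ["gA", "gB"]
        assert sig.good_genes == ["gD", "gC"]

    def test_twenty_gene_signature_is_distinct(self):
        rng = np.random.default_rng(3)
        disc = random_levels(rng, 200, 40)
        died = pd.Series(rng.random(40) < 0.5, index=disc.columns)
        scores = score_genes(disc, OutcomeLabels(died, 12.0))
        sig = build_signature(scores, _dummy_cis(disc.index), k_poor=10, k_good=10)
        assert sig.size == 20
        assert len(set(sig.genes)) == 20

    def test_single_gene_signature_is_the_argmax(self):
        t = TestRanking()._table({"gA": 6, "gB": 3, "gC": -2})
        sig = build_signature(t, _dummy_cis(["gA", "gB", "gC"]), k_poor=1, k_good=0)
        assert sig.poor_genes == ["gA"] and sig.good_genes == []

    def test_degenerate_overlap_resolved(self):
        # every score 0: both rankings start with the same gene
        t = TestRanking()._table({"gA": 0, "gB": 0, "gC": 0})
        sig = build_signature(t, _dummy_cis(["gA", "gB", "gC"]), k_poor=1, k_good=1)
        assert len(set(sig.genes)) == 2

    def test_invalid_sizes_rejected(self):
        t = TestRanking()._table({"gA": 1, "gB": 0})
        with pytest.raises(ValueError):
            build_signature(t, _dummy_cis(["gA", "gB"]), k_poor=0, k_good=0)
        with pytest.raises(ValueError):
            build_signature(t, _dummy_cis(["gA", "gB"]), k_poor=2, k_good=2)

    def test_overlapping_lists_rejected_by_signature(self):
        with pytest.raises(ValueError, match="both lists"):
            Signature(["gA"], ["gA"], _dummy_cis(["gA"]))


class TestRandomSignature:
    def test_sample_is_distinct_and_deterministic(self):
        ids = [f"g{i:05d}" for i in range(24000)]
        cis = _dummy_cis(ids)
        a = random_signature(ids, 10, 10, seed=7, cis=cis)
        b = random_signature(ids, 10, 10, seed=7, cis=cis)
        assert a.size == 20 and len(set(a.genes)) == 20
        assert a.genes == b.genes

    def test_different_seeds_differ(self):
        ids = [f"g{i:05d}" for i in range(24000)]
        cis = _dummy_cis(ids)
        sigs = {tuple(random_signature(ids, 10, 10, seed=s, cis=cis).genes) for s in range(8)}
        assert len(sigs) == 8


class TestSignatureSerialization:
    def test_round_trip(self, tmp_path):
        cis = _dummy_cis(["gA", "gB", "gC", "gD"])
        sig = Signature(
            ["gA", "gB"], ["gC", "gD"], cis, score_mode="discrete",
            cutoff=0.125, provenance={"n_training_patients": 144},
        )
        path = tmp_path / "sig.yaml"
        write_signature(sig, path)
        back = read_signature(path)
        assert back.poor_genes == sig.poor_genes
        assert back.good_genes == sig.good_genes
        assert back.score_mode == "discrete"
        assert back.cutoff == pytest.approx(0.125)
        assert back.provenance["n_training_patients"] == 144
        pd.testing.assert_frame_equal(
            back.cis.table[["mean", "ci_upper", "ci_lower"]].astype(float),
            sig.cis.table[["mean", "ci_upper", "ci_lower"]].astype(float),
            check_names=False,
        )
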