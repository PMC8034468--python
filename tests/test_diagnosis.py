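import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import reosig
from reosig import diagnosis, reo


class TestRankTransform:
    def test_ascending_ranks(self):
        ranks = diagnosis.rank_transform(pd.Series([0.5, 3.2, 1.1], index=list("abc")))
        assert list(ranks) == [1, 3, 2]

    def test_ties_get_midranks(self):
        ranks = diagnosis.rank_transform(pd.Series([2.0, 2.0, 5.0], index=list("abc")))
        assert list(ranks) == [1.5, 1.5, 3]

    def test_not_measured_genes_take_no_rank(self):
        ranks = diagnosis.rank_transform(
            pd.Series([2.0, np.nan, 5.0], index=list("abc"))
        )
        assert np.isnan(ranks["b"]) and list(ranks[["a", "c"]]) == [1, 2]

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=40))
    def test_ranks_sum_to_triangular_number(self, values):
        sample = pd.Series(values, index=[f"g{i}" for i in range(len(values))])
        n = len(values)
        assert diagnosis.rank_transform(sample).sum() == pytest.approx(n * (n + 1) / 2)

    def test_fewer_than_two_measured_genes_rejected(self):
        with pytest.raises(ValueError):
            diagnosis.rank_transform(pd.Series([1.0, np.nan], index=["a", "b"]))


class TestRankDifference:
    def test_signed_difference_and_antisymmetry(self):
        ranks = pd.Series({"a": 100.0, "b": 40.0})
        assert diagnosis.rank_difference(ranks, ("a", "b")) == 60
        assert diagnosis.rank_difference(ranks, ("b", "a")) == -60

    def test_unranked_gene_gives_nan(self):
        ranks = pd.Series({"a": 1.0, "b": np.nan})
        assert np.isnan(diagnosis.rank_difference(ranks, ("a", "b")))


class TestAvgRankDifference:
    @staticmethod
    def _matrix_with_rank_gaps(gaps: list[int]) -> pd.DataFrame:
        """One column per requested rank(a) - rank(b) gap over 7 genes."""
        genes = ["a", "b"] + [f"f{i}" for i in range(5)]
        cols = {}
        for j, gap in enumerate(gaps):
            values = np.zeros(7)
            # b at rank 1, a at rank 1 + gap (or reversed for negative gaps)
            ranks = {"b": 1, "a": 1 + gap} if gap >= 0 else {"a": 1, "b": 1 - gap}
            filler_ranks = [r for r in range(1, 8) if r not in ranks.values()]
            for gene, r in ranks.items():
                values[genes.index(gene)] = float(r)
            for gene, r in zip([g for g in genes if g not in ranks], filler_ranks):
                values[genes.index(gene)] = float(r)
            cols[f"s{j}"] = values
        return pd.DataFrame(cols, index=genes)

    def test_geometric_mean_of_absolute_group_means(self):
        # cancer rank differences {+3, +5}; normal {-2, -4}
        cancer = self._matrix_with_rank_gaps([3, 5])
        normal = self._matrix_with_rank_gaps([-2, -4])
        scored = diagnosis.avg_rank_difference(
            [("a", "b")], cancer, None, normal, None
        )
        row = scored.iloc[0]
        assert row.mean_rd_cancer == 4 and row.mean_rd_normal == -3
        assert row.avg_rd == pytest.approx(np.sqrt(12))

    def test_zero_mean_in_either_group_gives_zero_score(self):
        cancer = self._matrix_with_rank_gaps([2, -2])
        normal = self._matrix_with_rank_gaps([-3, -3])
        scored = diagnosis.avg_rank_difference([("a", "b")], cancer, None, normal, None)
        assert scored.avg_rd.iloc[0] == 0.0

    def test_score_invariant_to_swapping_the_genes(self):
        cancer = self._matrix_with_rank_gaps([3, 5])
        normal = self._matrix_with_rank_gaps([-2, -4])
        fwd = diagnosis.avg_rank_difference([("a", "b")], cancer, None, normal, None)
        rev = diagnosis.avg_rank_difference([("b", "a")], cancer, None, normal, None)
        assert fwd.avg_rd.iloc[0] == rev.avg_rd.iloc[0]

    def test_product_and_sqrt_rank_pairs_identically(self, rng):
        mc, mn = rng.uniform(-50, 50, 40), rng.uniform(-50, 50, 40)
        product = np.abs(mc) * np.abs(mn)
        sqrt = np.sqrt(product)
        assert list(np.argsort(product)) == list(np.argsort(sqrt))


class TestRemoveRedundantPairs:
    @staticmethod
    def _scored(rows):
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "avg_rd"])

    def test_greedy_trace(self):
        scored = self._scored(
            [("g1", "g2", 10.0), ("g1", "g3", 8.0), ("g4", "g5", 6.0)]
        )
        kept = diagnosis.remove_redundant_pairs(scored)
        assert list(zip(kept.gene_a, kept.gene_b)) == [("g1", "g2"), ("g4", "g5")]

    def test_disjoint_pairs_all_kept_in_score_order(self):
        scored = self._scored([("a", "b", 1.0), ("c", "d", 5.0)])
        kept = diagnosis.remove_redundant_pairs(scored)
        assert list(kept.gene_a) == ["c", "a"]

    def test_equal_scores_tie_broken_lexicographically(self):
        scored = self._scored([("g2", "g9", 5.0), ("g1", "g9", 5.0)])
        kept = diagnosis.remove_redundant_pairs(scored)
        assert list(zip(kept.gene_a, kept.gene_b)) == [("g1", "g9")]


@pytest.fixture(scope="module")
def clean_cohort():
    return reosig.simulate_cohort(
        reosig.SimulationConfig(seed=11, noise_sd=0.0, dropout_rate=0.0)
    )


@pytest.fixture(scope="module")
def signature(clean_cohort):
    ph = clean_cohort.phenotype
    return diagnosis.build_diagnosis_signature(
        clean_cohort.expression,
        ph.loc[(ph.group == "cancer") & (ph.stage == "I"), "sample_id"].tolist(),
        clean_cohort.expression,
        ph.loc[ph.group == "normal", "sample_id"].tolist(),
    )


class TestBuildAndClassify:

    def test_noise_free_signature_is_exactly_the_planted_pairs(
        self, clean_cohort, signature
    ):
        got = set(zip(signature.pairs.gene_a, signature.pairs.gene_b))
        assert got == set(clean_cohort.ground_truth.diag_pairs)

    def test_signature_genes_are_pairwise_distinct(self, signature):
        genes = list(signature.pairs.gene_a) + list(signature.pairs.gene_b)
        assert len(genes) == len(set(genes))

    def test_raising_threshold_never_enlarges_signature(self, clean_cohort):
        ph = clean_cohort.phenotype
        cancers = ph.loc[ph.group == "cancer", "sample_id"].tolist()
        normals = ph.loc[ph.group == "normal", "sample_id"].tolist()
        sizes = [
            len(
                diagnosis.build_diagnosis_signature(
                    clean_cohort.expression, cancers,
                    clean_cohort.expression, normals,
                    stable_threshold=t,
                )
            )
            for t in (0.9, 0.99, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_vote_cutoff_is_inclusive(self):
        pairs = pd.DataFrame(
            {"gene_a": [f"a{i}" for i in range(5)],
             "gene_b": [f"b{i}" for i in range(5)],
             "avg_rd": 1.0}
        )
        sig = diagnosis.DiagnosisSignature(pairs=pairs, vote_cutoff=0.60)
        values = {}
        for i in range(5):
            match = i < 3  # exactly 3/5 = 0.60
            values[f"a{i}"], values[f"b{i}"] = (2.0, 1.0) if match else (1.0, 2.0)
        label, result = diagnosis.classify_sample(pd.Series(values), sig)
        assert result.ratio == 0.6 and label == "CRC"
        # one fewer match drops below the cut-off
        values["a2"], values["b2"] = 1.0, 2.0
        label2, result2 = diagnosis.classify_sample(pd.Series(values), sig)
        assert result2.ratio == 0.4 and label2 == "non_cancer"

    def test_unmeasured_signature_gives_not_evaluable(self, signature):
        sample = pd.Series(
            np.nan, index=list(signature.pairs.gene_a) + list(signature.pairs.gene_b)
        )
        label, result = diagnosis.classify_sample(sample, signature)
        assert label == "not_evaluable" and result.m == 0

    def test_label_invariant_to_monotone_per_sample_transform(
        self, clean_cohort, signature
    ):
        sample = clean_cohort.expression.iloc[:, 0]
        base, _ = diagnosis.classify_sample(sample, signature)
        for transform in (lambda x: x**2, lambda x: np.sqrt(x), lambda x: 7 * x):
            assert diagnosis.classify_sample(transform(sample), signature)[0] == base

    def test_low_purity_mixtures_still_classify_as_cancer(self, clean_cohort, signature):
        from reosig.simulate import mix_purity

        ph = clean_cohort.phenotype
        tumor = clean_cohort.expression[
            ph.loc[ph.group == "cancer", "sample_id"].tolist()[0]
        ]
        normal = clean_cohort.expression[
            ph.loc[ph.group == "normal", "sample_id"].tolist()[0]
        ]
        mixed = mix_purity(tumor, normal, 0.6)
        assert diagnosis.classify_sample(mixed, signature)[0] == "CRC"

    def test_training_accuracy_is_perfect_on_noise_free_cohort(
        self, clean_cohort, signature
    ):
        table = diagnosis.evaluate_accuracy(
            clean_cohort.expression, clean_cohort.phenotype, signature
        ).set_index("group")
        assert table.loc["all", "accuracy_pct"] == 100.0


class TestEvaluateAccuracyArithmetic:
    def test_pool_counts_sums_before_dividing(self):
        assert diagnosis.pool_counts([(1, 2), (1, 2)]) == 50.0
        with pytest.raises(ValueError):
            diagnosis.pool_counts([(3, 2)])
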