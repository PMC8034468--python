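import numpy as np
import pandas as pd
import pytest

import reosig
from reosig import relapse


def _pairs(pair_list):
    return pd.DataFrame(pair_list, columns=["gene_a", "gene_b"])


class TestPartition:
    def test_published_block_layout_for_35349_candidates(self):
        assert relapse.partition_sizes(35349) == [3500, 4500, 5500, 6500, 7500, 7849]

    @pytest.mark.parametrize(
        "n, expected",
        [
            (8000, [3500, 4500]),
            (3000, [3000]),
            (0, []),
            (3501, [3500, 1]),
        ],
    )
    def test_exact_fit_and_remainder_blocks(self, n, expected):
        assert relapse.partition_sizes(n) == expected

    def test_blocks_are_disjoint_ordered_and_exhaustive(self):
        ranked = _pairs([(f"a{i}", f"b{i}") for i in range(23)])
        blocks = relapse.partition_candidates(ranked, base=5, step=3)
        assert [len(b) for b in blocks] == [5, 8, 10]
        rebuilt = pd.concat(blocks, ignore_index=True)
        pd.testing.assert_frame_equal(rebuilt, ranked)


class TestCoverageDifference:
    @staticmethod
    def _stage_matrix(n_greater: int, n_total: int) -> pd.DataFrame:
        cols = {}
        for i in range(n_total):
            cols[f"s{i}"] = [2.0, 1.0] if i < n_greater else [1.0, 2.0]
        return pd.DataFrame(cols, index=["x", "y"])

    def test_eq4_arithmetic(self):
        iv = self._stage_matrix(9, 10)
        i = self._stage_matrix(2, 10)
        out = relapse.coverage_difference(_pairs([("x", "y")]), iv, None, i, None)
        assert out.c_ivi.iloc[0] == pytest.approx(0.7)

    def test_identical_distributions_give_zero(self):
        m = self._stage_matrix(4, 10)
        out = relapse.coverage_difference(_pairs([("x", "y")]), m, None, m, None)
        assert out.c_ivi.iloc[0] == 0.0

    def test_antisymmetric_under_orientation_flip(self):
        iv, i = self._stage_matrix(9, 10), self._stage_matrix(2, 10)
        fwd = relapse.coverage_difference(_pairs([("x", "y")]), iv, None, i, None)
        rev = relapse.coverage_difference(_pairs([("y", "x")]), iv, None, i, None)
        assert fwd.c_ivi.iloc[0] == pytest.approx(-rev.c_ivi.iloc[0])

    def test_both_zero_samples_not_counted(self):
        iv = pd.DataFrame({"s0": [2.0, 1.0], "s1": [0.0, 0.0]}, index=["x", "y"])
        i = self._stage_matrix(0, 2)
        out = relapse.coverage_difference(_pairs([("x", "y")]), iv, None, i, None)
        assert out.coverage_iv.iloc[0] == 1.0  # 1 of 1 evaluable


class TestPairedConcordanceFilter:
    @staticmethod
    def _paired(n_concordant: int, n_pairs: int = 13, zero_pair: int | None = None):
        ff_cols, ffpe_cols, pairing = {}, {}, {}
        for i in range(n_pairs):
            ff_cols[f"ff{i}"] = [2.0, 1.0]
            if zero_pair == i:
                ffpe_cols[f"fp{i}"] = [0.0, 0.0]  # inevaluable in the FFPE member
            elif i < n_concordant:
                ffpe_cols[f"fp{i}"] = [3.0, 1.5]  # ordering preserved
            else:
                ffpe_cols[f"fp{i}"] = [1.0, 4.0]  # ordering flipped
            pairing[f"ff{i}"] = f"fp{i}"
        ff = pd.DataFrame(ff_cols, index=["x", "y"])
        ffpe = pd.DataFrame(ffpe_cols, index=["x", "y"])
        return ff, ffpe, pairing

    def test_ten_of_thirteen_kept_nine_dropped(self):
        pairs = _pairs([("x", "y")])
        ff, ffpe, pairing = self._paired(10)
        assert len(relapse.paired_concordance_filter(pairs, ff, ffpe, pairing)) == 1
        ff, ffpe, pairing = self._paired(9)
        assert len(relapse.paired_concordance_filter(pairs, ff, ffpe, pairing)) == 0

    def test_both_zero_member_does_not_count_as_concordant(self):
        pairs = _pairs([("x", "y")])
        ff, ffpe, pairing = self._paired(10, zero_pair=3)  # one concordant pair voided
        assert len(relapse.paired_concordance_filter(pairs, ff, ffpe, pairing)) == 0

    def test_empty_pairing_rejected(self):
        with pytest.raises(ValueError):
            relapse.paired_concordance_filter(
                _pairs([("x", "y")]), pd.DataFrame(), pd.DataFrame(), {}
            )


class TestPredictRelapse:
    @staticmethod
    def _signature_and_sample(n_match: int, n_pairs: int = 100):
        pairs = _pairs([(f"a{i}", f"b{i}") for i in range(n_pairs)])
        sig = relapse.RelapseSignature(pairs=pairs, vote_cutoff=0.49)
        values = {}
        for i in range(n_pairs):
            values[f"a{i}"], values[f"b{i}"] = (2.0, 1.0) if i < n_match else (1.0, 2.0)
        return sig, pd.Series(values)

    def test_strict_cutoff_boundary(self):
        sig, sample = self._signature_and_sample(50)
        assert relapse.predict_relapse(sample, sig)[0] == "high_risk"  # 0.50 > 0.49
        sig, sample = self._signature_and_sample(49)
        assert relapse.predict_relapse(sample, sig)[0] == "low_risk"  # 0.49 not > 0.49

    def test_zero_retention_is_low_risk(self):
        sig, sample = self._signature_and_sample(0)
        assert relapse.predict_relapse(sample, sig)[0] == "low_risk"

    def test_monotone_transform_invariance(self):
        sig, sample = self._signature_and_sample(60)
        assert relapse.predict_relapse(sample**3, sig)[0] == "high_risk"
        assert relapse.predict_relapse(np.sqrt(sample), sig)[0] == "high_risk"


class TestDegAnchoredPairs:
    def test_non_deg_pair_excluded_regardless_of_reversal(self, rng):
        genes = [f"g{i}" for i in range(8)]
        X = pd.DataFrame(
            rng.lognormal(1, 0.2, (8, 60)), index=genes,
            columns=[f"s{i}" for i in range(60)],
        )
        # fully reverse (g0, g1) between the two halves
        X.iloc[0, :30], X.iloc[1, :30] = 1.0, 100.0
        X.iloc[0, 30:], X.iloc[1, 30:] = 100.0, 1.0
        stage_i, stage_iv = list(X.columns[:30]), list(X.columns[30:])
        without = relapse.deg_anchored_opposite_pairs(
            X, stage_i, X, stage_iv, degs=["g5"], fdr=0.01
        )
        assert ("g0", "g1") not in set(zip(without.gene_a, without.gene_b))
        with_deg = relapse.deg_anchored_opposite_pairs(
            X, stage_i, X, stage_iv, degs=["g0"], fdr=0.01
        )
        assert ("g0", "g1") in set(zip(with_deg.gene_a, with_deg.gene_b))

    def test_loosening_fdr_gives_superset(self, rng):
        cohort = reosig.simulate_cohort(reosig.SimulationConfig(seed=5))
        ph = cohort.phenotype
        stage_i = ph.loc[ph.stage == "I", "sample_id"].tolist()
        stage_iv = ph.loc[ph.stage == "IV", "sample_id"].tolist()
        degs = cohort.ground_truth.deg_genes
        strict = relapse.deg_anchored_opposite_pairs(
            cohort.expression, stage_i, cohort.expression, stage_iv, degs, fdr=0.001
        )
        loose = relapse.deg_anchored_opposite_pairs(
            cohort.expression, stage_i, cohort.expression, stage_iv, degs, fdr=0.05
        )
        assert set(zip(strict.gene_a, strict.gene_b)) <= set(zip(loose.gene_a, loose.gene_b))

    def test_empty_deg_list_rejected(self):
        with pytest.raises(ValueError):
            relapse.deg_anchored_opposite_pairs(
                pd.DataFrame(), None, pd.DataFrame(), None, degs=[]
            )


class TestSelectRelapseSignature:
    @staticmethod
    def _separating_cohort(n_pairs: int, n_samples: int = 10):
        """Stage IV keeps every pattern, stage I none of them."""
        genes = [g for i in range(n_pairs) for g in (f"a{i}", f"b{i}")]
        iv = pd.DataFrame(
            {f"iv{j}": [v for _ in range(n_pairs) for v in (2.0, 1.0)] for j in range(n_samples)},
            index=genes,
        )
        i = pd.DataFrame(
            {f"i{j}": [v for _ in range(n_pairs) for v in (1.0, 2.0)] for j in range(n_samples)},
            index=genes,
        )
        pairs = _pairs([(f"a{k}", f"b{k}") for k in range(n_pairs)])
        return pairs, i, iv

    def test_larger_of_two_passing_blocks_chosen(self):
        pairs, stage_i, stage_iv = self._separating_cohort(8)
        blocks = [pairs.iloc[:3], pairs.iloc[3:]]  # sizes 3 and 5, both perfect
        signature, grid = relapse.select_relapse_signature(
            blocks, stage_i, None, stage_iv, None
        )
        assert signature.block_index == 1 and len(signature) == 5
        # every grid row should show the perfect separation
        assert (grid.acc_stage_i == 1.0).all() and (grid.acc_stage_iv == 1.0).all()

    def test_single_block_selected(self):
        pairs, stage_i, stage_iv = self._separating_cohort(4)
        signature, _ = relapse.select_relapse_signature(
            [pairs], stage_i, None, stage_iv, None
        )
        assert signature.block_index == 0

    def test_no_passing_block_warns_and_returns_best(self):
        pairs, stage_i, _ = self._separating_cohort(4)
        # both "stages" identical: stage IV accuracy collapses
        with pytest.warns(UserWarning):
            signature, grid = relapse.select_relapse_signature(
                [pairs], stage_i, None, stage_i, None
            )
        assert len(signature) == 4

    def test_planted_cohort_end_to_end_separates_latent_risk(self):
        from reosig import pipeline

        hits = 0
        for seed in (1, 2, 3):
            cohort = reosig.simulate_cohort(reosig.SimulationConfig(seed=seed))
            run = pipeline.run_relapse_pipeline(cohort, block_base=200, block_step=100)
            truth = cohort.ground_truth.high_risk
            pred = run.predictions
            acc = np.mean(
                [(pred.loc[s, "label"] == "high_risk") == truth[s] for s in pred.index]
            )
            hits += acc >= 0.8
        assert hits >= 2
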