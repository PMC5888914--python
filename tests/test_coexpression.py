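"""Replicate averaging, log transform, Pearson correlation and mutual rank."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aqnet import coexpression as cx
from oracles import mutual_rank_bruteforce


def _matrix(values, genes=None, cols=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = cols or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cols)


class TestAverageReplicates:
    def test_arithmetic_mean_of_replicates(self):
        m = _matrix([[2.0, 4.0, 10.0]], cols=["s1", "s2", "s3"])
        smap = pd.DataFrame({"sample_id": ["s1", "s2", "s3"],
                             "condition_id": ["c1", "c1", "c2"]})
        out = cx.average_replicates(m, smap)
        assert list(out.columns) == ["c1", "c2"]
        assert out.loc["g0", "c1"] == 3.0
        assert out.loc["g0", "c2"] == 10.0

    def test_single_replicate_is_identity_up_to_renaming(self, rng):
        m = _matrix(rng.uniform(0, 50, size=(4, 5)))
        smap = pd.DataFrame({"sample_id": m.columns,
                             "condition_id": [f"c{i}" for i in range(5)]})
        out = cx.average_replicates(m, smap)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy())

    def test_many_samples_collapse_to_conditions(self, rng):
        # 654 samples over 235 conditions (184 triplicates + 51 duplicates)
        reps = [3] * 184 + [2] * 51
        samples, conds = [], []
        for c, r in enumerate(reps):
            for j in range(r):
                samples.append(f"c{c}_r{j}")
                conds.append(f"c{c}")
        assert len(samples) == 654
        m = _matrix(rng.uniform(0, 10, size=(3, 654)), cols=samples)
        out = cx.average_replicates(m, pd.DataFrame({"sample_id": samples,
                                                     "condition_id": conds}))
        assert out.shape == (3, 235)

    def test_unmapped_column_is_an_error_naming_it(self):
        m = _matrix([[1.0, 2.0]], cols=["s1", "mystery"])
        smap = pd.DataFrame({"sample_id": ["s1"], "condition_id": ["c1"]})
        with pytest.raises(ValueError, match="mystery"):
            cx.average_replicates(m, smap)


class TestLogTransform:
    @pytest.mark.parametrize("raw,expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
    def test_log2_plus_one(self, raw, expected):
        out = cx.log_transform(_matrix([[raw]]))
        assert out.iloc[0, 0] == pytest.approx(expected)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            cx.log_transform(_matrix([[-0.5]]))


class TestPccMatrix:
    def test_affine_copy_and_negation(self, rng):
        base = rng.uniform(1, 9, size=8)
        m = _matrix([base, 2 * base + 3, base.max() + 1 - base])
        corr = cx.pcc_matrix(m)
        assert corr.loc["g0", "g1"] == pytest.approx(1.0)
        assert corr.loc["g0", "g2"] == pytest.approx(-1.0)

    def test_matches_definitional_formula(self, rng):
        m = _matrix(rng.uniform(0, 5, size=(10, 5)))
        corr = cx.pcc_matrix(m)
        x = m.to_numpy()
        centered = x - x.mean(axis=1, keepdims=True)
        for i in range(10):
            for j in range(10):
                expected = (centered[i] @ centered[j]) / (
                    np.sqrt((centered[i] ** 2).sum())
                    * np.sqrt((centered[j] ** 2).sum()))
                assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_excluded_with_warning(self, rng, caplog):
        m = _matrix(np.vstack([rng.uniform(0, 5, size=(3, 6)),
                               np.full(6, 2.0)]))
        with caplog.at_level("WARNING"):
            corr = cx.pcc_matrix(m)
        assert "g3" not in corr.index
        assert "zero-variance" in caplog.text

    def test_too_few_conditions_rejected(self, rng):
        with pytest.raises(ValueError, match="3 conditions"):
            cx.pcc_matrix(_matrix(rng.uniform(0, 5, size=(4, 2))))


class TestMutualRank:
    def test_reciprocal_best_pair_has_mr_one(self, toy_corr):
        edge = cx.mutual_rank(toy_corr, "a", "b")
        assert edge.mr == pytest.approx(1.0)

    def test_known_rank_product(self):
        # hand-built correlations: rank_a(b) = 2, rank_b(a) = 8 -> mr = 4
        genes = [f"g{i}" for i in range(10)]
        corr = pd.DataFrame(np.zeros((10, 10)), index=genes, columns=genes)
        np.fill_diagonal(corr.values, 1.0)
        a, b = "g0", "g1"
        corr.loc[a, "g2"] = corr.loc["g2", a] = 0.9   # a's rank-1 partner
        corr.loc[a, b] = corr.loc[b, a] = 0.5         # a's rank-2 partner
        for i, g in enumerate(["g2", "g3", "g4", "g5", "g6", "g7", "g8"]):
            corr.loc[b, g] = corr.loc[g, b] = 0.95 - 0.01 * i  # b's ranks 1..7
        edge = cx.mutual_rank(corr, a, b)
        assert edge.mr == pytest.approx(4.0)

    def test_matches_bruteforce_on_all_pairs(self, rng):
        m = pd.DataFrame(rng.uniform(0, 5, size=(12, 8)),
                         index=[f"g{i:02d}" for i in range(12)])
        corr = cx.pcc_matrix(m)
        for a in corr.index:
            for b in corr.index:
                if a < b:
                    edge = cx.mutual_rank(corr, a, b)
                    assert edge.mr == pytest.approx(
                        mutual_rank_bruteforce(corr, a, b))

    def test_symmetry(self, toy_corr):
        for a in toy_corr.index:
            for b in toy_corr.index:
                if a < b:
                    assert cx.mutual_rank(toy_corr, a, b).mr == pytest.approx(
                        cx.mutual_rank(toy_corr, b, a).mr)
                    assert cx.mutual_rank(toy_corr, a, b).mr >= 1.0

    def test_unknown_gene_rejected(self, toy_corr):
        with pytest.raises(ValueError, match="nope"):
            cx.mutual_rank(toy_corr, "a", "nope")


class TestGuideNeighborhood:
    def test_truncates_to_rankable_universe(self, toy_corr):
        hood = cx.guide_neighborhood(toy_corr, "a", k=500)
        assert len(hood) == len(toy_corr) - 1

    def test_agrees_with_pairwise_mutual_rank(self, rng):
        m = pd.DataFrame(rng.uniform(0, 5, size=(15, 10)),
                         index=[f"g{i:02d}" for i in range(15)])
        corr = cx.pcc_matrix(m)
        hood = cx.guide_neighborhood(corr, "g00", k=14)
        for rec in hood.entries.itertuples(index=False):
            assert rec.mr == pytest.approx(
                cx.mutual_rank(corr, "g00", rec.gene).mr)

    def test_recovers_planted_module(self, small_config):
        from aqnet.synthetic import gen_expression

        m, smap, truth = gen_expression(small_config)
        logged = cx.log_transform(cx.average_replicates(m, smap))
        hood = cx.guide_neighborhood(cx.pcc_matrix(logged), small_config.guide,
                                     k=small_config.module_size)
        members = set(truth.module_members) - {small_config.guide}
        assert len(set(hood.genes) & members) >= len(members) - 1

    def test_gene_order_permutation_invariance(self, rng):
        m = pd.DataFrame(rng.uniform(0, 5, size=(20, 12)),
                         index=[f"g{i:02d}" for i in range(20)])
        hood1 = cx.guide_neighborhood(cx.pcc_matrix(m), "g05", k=10)
        perm = m.sample(frac=1, random_state=7)
        hood2 = cx.guide_neighborhood(cx.pcc_matrix(perm), "g05", k=10)
        pairs1 = {(r.gene, round(r.mr, 9)) for r in hood1.entries.itertuples()}
        pairs2 = {(r.gene, round(r.mr, 9)) for r in hood2.entries.itertuples()}
        assert pairs1 == pairs2

    @given(st.integers(1, 6))
    def test_entries_sorted_ascending_mr(self, k):
        rng = np.random.default_rng(99)
        m = pd.DataFrame(rng.uniform(0, 5, size=(8, 6)),
                         index=[f"g{i}" for i in range(8)])
        hood = cx.guide_neighborhood(cx.pcc_matrix(m), "g0", k=k)
        mrs = list(hood.entries["mr"])
        assert mrs == sorted(mrs)
        assert len(hood) <= k
        assert "g0" not in hood.genes
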