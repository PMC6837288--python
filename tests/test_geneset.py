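"""Tests for normalization, fold-changes, and the K-S permutation machinery."""

import numpy as np
import pytest

from altipop.geneset_shift import (
    ExpressionCounts,
    bh_fdr,
    directional_contrast,
    filter_low_expression,
    geneset_shift_test,
    ks_shift,
    log_fold_change,
    normalized_counts,
    permutation_null,
    tmm_factors,
)
from altipop.synthetic_data import SyntheticExpressionConfig, gen_expression_counts


def make_ec(counts, genotypes=None):
    counts = np.asarray(counts)
    g, s = counts.shape
    return ExpressionCounts(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(g)],
        sample_ids=[f"s{j}" for j in range(s)],
        genotypes=genotypes or ["LL"] * (s // 2) + ["HH"] * (s - s // 2),
    )


class TestFilter:
    def test_boundary_gene_kept(self):
        ec = make_ec(np.vstack([np.full(4, 10), np.full(4, 1000)]))
        kept = filter_low_expression(ec, 10.0)
        assert "g0" in kept.gene_ids

    def test_all_zero_gene_removed(self):
        ec = make_ec(np.vstack([np.zeros(4, int), np.full(4, 100)]))
        kept = filter_low_expression(ec, 10.0)
        assert kept.gene_ids == ["g1"]

    def test_library_size_normalization(self):
        # libraries (100, 300), gene counts (5, 15) -> normalized (10, 10)
        counts = np.array([[5, 15], [95, 285]])
        ec = make_ec(counts)
        kept = filter_low_expression(ec, 10.0)
        assert "g0" in kept.gene_ids
        kept2 = filter_low_expression(ec, 10.0 + 1e-9)
        assert "g0" not in kept2.gene_ids


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 1000, size=200)
        ec = make_ec(np.tile(col[:, None], (1, 4)))
        assert tmm_factors(ec) == pytest.approx(np.ones(4), abs=1e-9)

    def test_pure_depth_scaling_gives_unit_factors(self):
        # doubling every count doubles the library size; composition is
        # unchanged, so TMM must return unit factors
        rng = np.random.default_rng(2)
        col = rng.integers(10, 1000, size=200)
        ec = make_ec(np.stack([col, 2 * col], axis=1))
        assert tmm_factors(ec) == pytest.approx(np.ones(2), abs=1e-6)

    def test_composition_bias_hand_oracle(self):
        # 200 genes identical; one extra gene hugely expressed in sample 2
        # only.  For sample 2 vs reference 1 all shared genes have
        # M = log2((c/N2)/(c/N1)) = log2(N1/N2), constant, so the trimmed
        # weighted mean is exactly that and factors are (g, 1/g) with
        # g = 2**(-M/2).
        col = np.full(200, 100)
        counts = np.stack([np.append(col, 0), np.append(col, 20_000)],
                          axis=1)
        ec = make_ec(counts)
        n1, n2 = 20_000, 40_000
        m = np.log2(n1 / n2)
        g = 2.0 ** (m / 2)
        f = tmm_factors(ec)
        assert f[1] / f[0] == pytest.approx(2.0 ** m, rel=1e-6)
        assert np.prod(f) == pytest.approx(1.0, abs=1e-9)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        ec = make_ec(rng.integers(0, 500, size=(300, 6)))
        f = tmm_factors(ec)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)


class TestLogFoldChange:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(4)
        col = rng.integers(1, 500, size=100)
        ec = make_ec(np.tile(col[:, None], (1, 6)),
                     ["LL"] * 3 + ["HH"] * 3)
        lfc = log_fold_change(ec, ("HH", "LL"))
        assert lfc == pytest.approx(np.zeros(100), abs=1e-9)

    def test_hand_arithmetic_40_vs_10(self):
        # unit factors and equal library sizes: normalization is a no-op
        counts = np.array([[40, 40, 10, 10], [60, 60, 90, 90]])
        ec = make_ec(counts, ["HH", "HH", "LL", "LL"])
        lfc = log_fold_change(ec, ("HH", "LL"), prior_count=0.5,
                              factors=np.ones(4))
        assert lfc[0] == pytest.approx(np.log2(40.5 / 10.5), abs=1e-9)
        assert lfc[0] == pytest.approx(1.94753, abs=1e-5)

    def test_common_library_scaling_leaves_lfc_unchanged(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 300, size=(80, 6))
        ec1 = make_ec(counts, ["LL"] * 3 + ["HH"] * 3)
        ec2 = make_ec(counts * 7, ["LL"] * 3 + ["HH"] * 3)
        a = log_fold_change(ec1, ("HH", "LL"), factors=np.ones(6))
        b = log_fold_change(ec2, ("HH", "LL"), factors=np.ones(6))
        # invariance is exact only in the zero-prior limit; the fixed prior
        # count shrinks relative to rescaled means, perturbing low-count
        # genes slightly
        assert a == pytest.approx(b, abs=0.1)


def ks_d_bruteforce(a, b):
    """Double-loop ECDF comparison at every pooled point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        d = abs(np.mean(a <= x) - np.mean(b <= x))
        best = max(best, d)
    return best


class TestKsShift:
    def test_identical_vectors(self):
        d, _, _ = ks_shift([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, sign, p = ks_shift([1, 2, 3], [4, 5, 6])
        assert d == 1.0 and sign == -1

    def test_interleaved(self):
        d, _, _ = ks_shift([1, 3], [2, 4])
        assert d == pytest.approx(0.5)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 20))
            b = rng.normal(size=rng.integers(2, 20))
            d, _, _ = ks_shift(a, b)
            assert d == pytest.approx(ks_d_bruteforce(a, b), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_shift([], [1.0])


class TestPermutationNull:
    def test_fixed_seed_identical(self):
        lfc = np.random.default_rng(7).normal(size=500)
        a, qa = permutation_null(lfc, 30, 200, rng=9)
        b, qb = permutation_null(lfc, 30, 200, rng=9)
        assert np.array_equal(a, b) and qa == qb

    def test_null_d_matches_direct_ks(self):
        rng = np.random.default_rng(8)
        lfc = rng.normal(size=300)
        ds, _ = permutation_null(lfc, 20, 100, rng=10)
        # permutation D values live in the same range as direct K-S draws
        direct = []
        for _ in range(100):
            pick = rng.choice(300, 20, replace=False)
            mask = np.zeros(300, bool)
            mask[pick] = True
            direct.append(ks_d_bruteforce(lfc[mask], lfc[~mask]))
        assert abs(np.median(ds) - np.median(direct)) < 0.05

    def test_q99_decreases_with_set_size(self):
        rng = np.random.default_rng(11)
        lfc = rng.normal(size=3000)
        qs = [permutation_null(lfc, s, 300, rng=12)[1]
              for s in (10, 100, 1000)]
        assert qs[0] > qs[1] > qs[2]

    def test_degenerate_one_gene_background(self):
        lfc = np.random.default_rng(13).normal(size=50)
        ds, _ = permutation_null(lfc, 49, 100, rng=14)
        assert (ds <= 1.0).all() and ds.mean() < 1.0


class TestGenesetShiftTest:
    def test_detects_injected_shift(self):
        cfg = SyntheticExpressionConfig(n_genes=2000, candidate_size=60,
                                        shift=0.5, seed=100,
                                        group_sizes={"LL": 6, "HH": 6})
        ec, cand = gen_expression_counts(cfg)
        res = geneset_shift_test(ec, cand, ("HH", "LL"), n_perm=300, rng=1)
        assert res.exceeds_q99
        assert res.shift_sign == 1

    def test_invariant_to_gene_and_sample_order(self):
        cfg = SyntheticExpressionConfig(n_genes=400, candidate_size=30,
                                        shift=0.4, seed=101,
                                        group_sizes={"LL": 4, "HH": 4})
        ec, cand = gen_expression_counts(cfg)
        rng = np.random.default_rng(2)
        gperm = rng.permutation(ec.n_genes)
        ec_shuf = ExpressionCounts(
            counts=ec.counts[gperm, :],
            gene_ids=[ec.gene_ids[i] for i in gperm],
            sample_ids=ec.sample_ids,
            genotypes=ec.genotypes)
        a = geneset_shift_test(ec, cand, ("HH", "LL"), n_perm=200, rng=3)
        b = geneset_shift_test(ec_shuf, cand, ("HH", "LL"), n_perm=200,
                               rng=3)
        assert a.d_statistic == pytest.approx(b.d_statistic, abs=1e-12)
        assert a.null_q99 == pytest.approx(b.null_q99, abs=1e-12)

    def test_too_few_candidates_rejected(self):
        cfg = SyntheticExpressionConfig(n_genes=300, candidate_size=10,
                                        seed=102,
                                        group_sizes={"LL": 3, "HH": 3})
        ec, _ = gen_expression_counts(cfg)
        with pytest.raises(ValueError):
            geneset_shift_test(ec, ["nonexistent1", "nonexistent2"],
                               ("HH", "LL"), rng=4)


class TestDirectionalContrast:
    def test_identical_sets(self):
        lfc = {f"p{i}": 0.5 for i in range(3)}
        lfc.update({f"n{i}": 0.5 for i in range(3)})
        (mp, _), (mn, _), p = directional_contrast(
            lfc, [f"p{i}" for i in range(3)], [f"n{i}" for i in range(3)],
            n_perm=500, rng=1)
        assert mp == mn
        assert p == pytest.approx(1.0, abs=0.05)

    def test_extreme_separation_minimal_p(self):
        lfc = {f"p{i}": 1.0 for i in range(3)}
        lfc.update({f"n{i}": -1.0 for i in range(3)})
        (mp, sp), (mn, sn), p = directional_contrast(
            lfc, [f"p{i}" for i in range(3)], [f"n{i}" for i in range(3)],
            n_perm=2000, rng=2)
        assert mp - mn == pytest.approx(2.0)
        assert sp == 0.0 and sn == 0.0
        # 20 label assignments, 2 are as extreme -> p ~ 0.1
        assert p == pytest.approx(0.1, abs=0.05)

    def test_overlap_rejected(self):
        lfc = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 0.0}
        with pytest.raises(ValueError):
            directional_contrast(lfc, ["a", "b"], ["b", "c"])


def test_bh_fdr_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.04, 0.2, 0.9])
    q = bh_fdr(p)
    assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()
    assert (q >= p - 1e-12).all() and (q <= 1.0).all()


def test_per_gene_de_flags_strong_signal_and_controls_nulls():
    rng = np.random.default_rng(17)
    base = rng.integers(50, 500, size=40)
    counts = np.tile(base[:, None], (1, 8))
    counts = rng.poisson(counts)
    counts[0, 4:] *= 6  # one strongly shifted gene in group HH
    from altipop.geneset_shift import per_gene_de

    ec = make_ec(counts, ["LL"] * 4 + ["HH"] * 4)
    table = per_gene_de(ec, ("HH", "LL"))
    assert table.loc[0, "q"] < 0.01
    assert table.loc[0, "lfc"] > 1.5
    assert (table["q"] >= table["p"] - 1e-12).all()
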