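import math
import subprocess

import numpy as np
import pytest

from tmmnorm import (
    CountMatrix,
    TMMError,
    TrimParams,
    compute_ma,
    doubly_trim,
    effective_sizes_two_sample,
    tmm_factor,
    tmm_factors,
)

from _oracles import oracle_tmm_log2_factor
from conftest import random_count_matrix


class TestComputeMA:
    def test_formulas_match_arbitrary_precision_evaluation(self):
        # direct evaluation of M, A, var(M) with sympy rationals
        sympy = pytest.importorskip("sympy")
        yk, yr = (10, 100, 1000), (20, 100, 880)
        cm = CountMatrix(("g1", "g2", "g3"), ("k", "r"), np.array(list(zip(yk, yr))))
        nk, nr = 1110, 1000
        ma = compute_ma(cm, "k", "r")
        for i in range(3):
            pk = sympy.Rational(yk[i], nk)
            pr = sympy.Rational(yr[i], nr)
            m_exact = float(sympy.log(pk / pr, 2).evalf(30))
            a_exact = float((sympy.log(pk * pr, 2) / 2).evalf(30))
            v_exact = float(
                (
                    sympy.Rational(nk - yk[i], nk * yk[i])
                    + sympy.Rational(nr - yr[i], nr * yr[i])
                ).evalf(30)
            )
            assert ma.M[i] == pytest.approx(m_exact, abs=1e-12)
            assert ma.A[i] == pytest.approx(a_exact, abs=1e-12)
            assert ma.var_M[i] == pytest.approx(v_exact, rel=1e-12)
            assert ma.weight[i] == pytest.approx(1 / v_exact, rel=1e-12)

    def test_self_comparison_has_zero_m_and_own_abundance(self, small_counts):
        ma = compute_ma(small_counts, "L1", "L1")
        valid = ma.valid
        assert np.allclose(ma.M[valid], 0.0)
        y = small_counts.column("L1")[valid]
        n = small_counts.library_size("L1")
        assert np.allclose(ma.A[valid], np.log2(y / n))

    def test_zero_count_flags_gene_invalid(self, small_counts):
        ma = compute_ma(small_counts, "L1", "L2")
        assert not ma.valid[2]  # g3 has Y=0 in L1
        assert np.isnan(ma.M[2])
        assert ma.valid[:2].all()

    def test_count_equal_to_library_size_excluded_with_warning(self):
        cm = CountMatrix(("g1",), ("a", "b"), np.array([[5, 7]]))
        with pytest.warns(UserWarning, match="library size"):
            ma = compute_ma(cm, "a", "b")
        assert ma.n_valid == 0

    def test_unknown_library_raises(self, small_counts):
        with pytest.raises(KeyError):
            compute_ma(small_counts, "L1", "nope")


class TestDoublyTrim:
    def test_zero_trim_keeps_all_valid_genes(self, rng):
        cm = random_count_matrix(rng, n_genes=50)
        ma = compute_ma(cm, "lib0", "lib1")
        kept = doubly_trim(ma, TrimParams(m_trim=0.0, a_trim=0.0))
        assert set(kept) == set(np.asarray(ma.gene_ids)[ma.valid])

    def test_thirty_percent_m_trim_removes_three_per_tail_of_ten(self):
        # 10 genes with distinct M: counts chosen so M is strictly increasing
        yk = np.array([1, 2, 4, 8, 16, 32, 64, 128, 256, 512]) * 10
        yr = np.full(10, 100)
        cm = CountMatrix(
            tuple(f"g{i}" for i in range(10)), ("k", "r"), np.column_stack([yk, yr])
        )
        ma = compute_ma(cm, "k", "r")
        kept = doubly_trim(ma, TrimParams(m_trim=0.3, a_trim=0.0))
        order = np.argsort(ma.M)
        expected = set(np.asarray(ma.gene_ids)[order[3:7]])
        assert set(kept) == expected
        assert len(kept) == 4

    def test_matches_brute_force_oracle_on_distinct_values(self, rng):
        cm = random_count_matrix(rng, n_genes=100)
        ma = compute_ma(cm, "lib0", "lib1")
        kept = set(doubly_trim(ma))
        # oracle: exhaustive sort-and-slice over the same candidate pool
        n = ma.n_valid
        m, a = ma.M[ma.valid], ma.A[ma.valid]
        ids = np.asarray(ma.gene_ids)[ma.valid]
        lo_m, hi_m = math.floor(n * 0.3) + 1, n - math.floor(n * 0.3)
        lo_a, hi_a = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
        rank_m = {ids[i]: j + 1 for j, i in enumerate(np.argsort(m))}
        rank_a = {ids[i]: j + 1 for j, i in enumerate(np.argsort(a))}
        expected = {
            g for g in ids
            if lo_m <= rank_m[g] <= hi_m and lo_a <= rank_a[g] <= hi_a
        }
        assert kept == expected

    def test_a_min_floor_removes_low_abundance_genes(self, rng):
        cm = random_count_matrix(rng, n_genes=100)
        ma = compute_ma(cm, "lib0", "lib1")
        floor_a = float(np.nanmedian(ma.A))
        kept = doubly_trim(ma, TrimParams(m_trim=0.0, a_trim=0.0, a_min=floor_a))
        assert all(ma.A[list(ma.gene_ids).index(g)] >= floor_a for g in kept)

    def test_overtrimming_raises_helpful_error(self):
        # three genes whose M-middle is not the A-middle: with 40% trims the
        # two keep-sets are disjoint and G* is empty
        cm = CountMatrix(
            ("g1", "g2", "g3"),
            ("k", "r"),
            np.array([[1000, 10], [4, 4], [10, 1000]]),
        )
        with pytest.raises(TMMError, match="smaller"):
            doubly_trim(compute_ma(cm, "k", "r"), TrimParams(m_trim=0.4, a_trim=0.4))


class TestTMMFactor:
    def test_self_comparison_gives_factor_one_exactly(self, rng):
        cm = random_count_matrix(rng, n_genes=120)
        res = tmm_factor(cm, "lib0", "lib0")
        assert res.log2_factor == 0.0
        assert res.factor == 1.0
        assert res.production_ratio == 1.0

    def test_uniform_scaling_of_one_library_gives_factor_one(self, rng):
        y = rng.poisson(200, size=150) + 1
        cm = CountMatrix(
            tuple(f"g{i}" for i in range(150)),
            ("k", "r"),
            np.column_stack([y, y * 3]),
        )
        res = tmm_factor(cm, "k", "r")
        assert res.factor == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            cm = random_count_matrix(rng, n_genes=200)
            res = tmm_factor(cm, "lib0", "lib1")
            expected = oracle_tmm_log2_factor(
                list(cm.column("lib0")),
                list(cm.column("lib1")),
                cm.library_size("lib0"),
                cm.library_size("lib1"),
            )
            assert res.log2_factor == pytest.approx(expected, abs=1e-12)

    def test_unweighted_mean_matches_oracle(self, rng):
        cm = random_count_matrix(rng, n_genes=200)
        params = TrimParams(weighted=False)
        res = tmm_factor(cm, "lib0", "lib1", params)
        expected = oracle_tmm_log2_factor(
            list(cm.column("lib0")),
            list(cm.column("lib1")),
            cm.library_size("lib0"),
            cm.library_size("lib1"),
            weighted=False,
        )
        assert res.log2_factor == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry_is_exact(self, rng):
        for _ in range(10):
            cm = random_count_matrix(rng, n_genes=150)
            ab = tmm_factor(cm, "lib0", "lib1")
            ba = tmm_factor(cm, "lib1", "lib0")
            assert ab.log2_factor == pytest.approx(-ba.log2_factor, abs=1e-12)
            assert set(ab.kept_genes) == set(ba.kept_genes)

    def test_scale_invariance_under_whole_matrix_scaling(self, rng):
        # scaling every count leaves proportions unchanged and scales every
        # delta-method weight by 1/c, so the weighted factor is invariant
        cm = random_count_matrix(rng, n_genes=150)
        scaled = CountMatrix(cm.gene_ids, cm.library_ids, cm.counts * 7)
        r1 = tmm_factor(cm, "lib0", "lib1")
        r2 = tmm_factor(scaled, "lib0", "lib1")
        assert r2.log2_factor == pytest.approx(r1.log2_factor, abs=1e-9)

    def test_one_library_scaling_exact_for_unweighted_mean(self, rng):
        # scaling a single library (size recomputed) leaves M, A and the trim
        # set bitwise unchanged; the unweighted factor is therefore exact.
        # The weighted factor shifts slightly because only that library's
        # variance term shrinks, so the precision weights re-balance.
        cm = random_count_matrix(rng, n_genes=150)
        scaled = CountMatrix(
            cm.gene_ids,
            cm.library_ids,
            np.column_stack([cm.column("lib0") * 7, cm.column("lib1")]),
        )
        params = TrimParams(weighted=False)
        r1 = tmm_factor(cm, "lib0", "lib1", params)
        r2 = tmm_factor(scaled, "lib0", "lib1", params)
        assert r2.log2_factor == r1.log2_factor
        w1 = tmm_factor(cm, "lib0", "lib1")
        w2 = tmm_factor(scaled, "lib0", "lib1")
        assert set(w1.kept_genes) == set(w2.kept_genes)
        assert w2.log2_factor == pytest.approx(w1.log2_factor, abs=0.05)

    def test_matches_edger_reference_implementation(self, rng):
        """Cross-check the pairwise factor against edgeR's TMM via Rscript."""
        cm = random_count_matrix(rng, n_genes=300, mean=500)
        res = tmm_factor(cm, "lib0", "lib1")
        rcode = f"""
        suppressMessages(library(edgeR))
        obs <- c({','.join(map(str, cm.column('lib0')))})
        ref <- c({','.join(map(str, cm.column('lib1')))})
        f <- edgeR:::.calcFactorTMM(obs, ref,
            libsize.obs={cm.library_size('lib0')}, libsize.ref={cm.library_size('lib1')},
            logratioTrim=0.3, sumTrim=0.05, doWeighting=TRUE, Acutoff=-1e10)
        cat(sprintf("%.15f", f))
        """
        proc = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=120
        )
        if proc.returncode != 0:
            pytest.skip(f"Rscript/edgeR unavailable: {proc.stderr[:200]}")
        assert res.factor == pytest.approx(float(proc.stdout), rel=1e-9)


class TestMultiSample:
    def test_identical_libraries_all_factors_one(self, rng):
        y = rng.poisson(100, size=100) + 1
        cm = CountMatrix(
            tuple(f"g{i}" for i in range(100)),
            ("a", "b", "c"),
            np.column_stack([y, y * 2, y * 5]),
        )
        nf = tmm_factors(cm, reference="a")
        assert nf.reference_id == "a"
        assert np.allclose(nf.factors, 1.0, atol=1e-12)
        assert np.allclose(nf.effective_sizes, cm.library_sizes * nf.factors)

    def test_consistency_with_pairwise_factor(self, rng):
        cm = random_count_matrix(rng, n_genes=200, n_libs=3)
        nf = tmm_factors(cm, reference="lib0")
        for lib in ("lib1", "lib2"):
            assert nf.factor(lib) == tmm_factor(cm, lib, "lib0").factor
        assert nf.factor("lib0") == 1.0

    def test_auto_reference_is_deterministic(self, rng):
        cm = random_count_matrix(rng, n_genes=200, n_libs=3)
        assert tmm_factors(cm).reference_id == tmm_factors(cm).reference_id

    def test_single_library_rejected(self, rng):
        cm = random_count_matrix(rng, n_genes=20, n_libs=1)
        with pytest.raises(TMMError, match="two libraries"):
            tmm_factors(cm)


class TestEffectiveSizes:
    def test_factor_one_leaves_sizes_unchanged(self):
        assert effective_sizes_two_sample(1e6, 2e6, 1.0) == (1e6, 2e6)

    def test_quarter_factor_splits_as_square_root(self):
        nk, nr = effective_sizes_two_sample(1e6, 1e6, 0.25)
        assert nk == pytest.approx(5e5)
        assert nr == pytest.approx(2e6)
        assert nk / nr == pytest.approx(0.25)

    def test_square_root_split_preserves_product(self, rng):
        for _ in range(20):
            a, b = rng.uniform(1e4, 1e7, 2)
            f = rng.uniform(0.1, 10)
            nk, nr = effective_sizes_two_sample(a, b, f)
            assert nk * nr == pytest.approx(a * b, rel=1e-12)
            assert nk / nr == pytest.approx(a / b * f, rel=1e-12)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(TMMError):
            effective_sizes_two_sample(0, 1e6, 1.0)
        with pytest.raises(TMMError):
            effective_sizes_two_sample(1e6, 1e6, -2.0)
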