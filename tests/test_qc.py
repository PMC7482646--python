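import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from growthpanel.qc import (
    call_rate_filter,
    genotype_counts,
    heterozygosity_filter,
    hwe_exact_test,
    ld_prune,
    ld_r2,
    pca_covariates,
    run_qc,
)
from growthpanel.records import MISSING, GenotypeMatrix, VariantRecord
from growthpanel.simulate import CohortSimConfig, simulate_cohort
from tests.conftest import make_matrix


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-fraction enumeration of the conditional heterozygote
    distribution under Hardy-Weinberg, independent of the implementation."""
    n = n_aa + n_ab + n_bb
    rare = 2 * min(n_aa, n_bb) + n_ab
    if rare == 0:
        return 1.0
    denom = math.comb(2 * n, rare)
    probs = {}
    for het in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        num = (
            math.factorial(n)
            // (math.factorial(hom_rare) * math.factorial(het) * math.factorial(hom_common))
        ) * (2 ** het)
        probs[het] = Fraction(num, denom)
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_5_0_5_matches_enumeration(self):
        assert hwe_exact_test(5, 0, 5) == pytest.approx(
            hwe_enumeration_oracle(5, 0, 5), rel=1e-9
        )

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n_aa=st.integers(0, 15), n_ab=st.integers(0, 15), n_bb=st.integers(0, 15)
    )
    def test_matches_enumeration_oracle(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
            hwe_enumeration_oracle(n_aa, n_ab, n_bb), rel=1e-9, abs=1e-12
        )


class TestCallRateFilter:
    def test_sample_at_threshold_kept_below_removed(self):
        # 5 variants: 4/5 = 80% kept; 3/5 = 60% removed at the 75% default
        d = [
            [0, 1, 0, 1, MISSING],
            [MISSING, MISSING, 0, 1, 0],
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
        ]
        m = make_matrix(d)
        out, removed_s, removed_v = call_rate_filter(m)
        assert "s0" not in removed_s  # 80%
        assert "s1" in removed_s      # 60%

    def test_no_missingness_identity(self):
        m = make_matrix([[0, 1], [1, 2]])
        out, rs, rv = call_rate_filter(m)
        assert out == m and not rs and not rv

    def test_everything_removed_errors(self):
        m = make_matrix([[MISSING], [MISSING]])
        with pytest.raises(ValueError, match="no data"):
            call_rate_filter(m)


class TestHeterozygosityFilter:
    def test_identical_rates_none_removed(self):
        m = make_matrix([[1, 0], [1, 0], [1, 0]])
        assert heterozygosity_filter(m) == []

    def test_extreme_outlier_removed(self):
        rng = np.random.default_rng(0)
        d = (rng.random((100, 50)) < 0.2).astype(np.int8)  # het rate ~0.2
        d[0, :] = 1  # het rate 1.0
        m = make_matrix(d)
        assert "s0" in heterozygosity_filter(m)

    def test_infinite_k_none_removed(self):
        m = make_matrix([[1, 0], [0, 0], [1, 1]])
        assert heterozygosity_filter(m, k=np.inf) == []


class TestLdR2:
    def test_column_with_itself_is_one(self):
        x = np.array([0, 1, 2, 1, 0])
        assert ld_r2(x, x) == pytest.approx(1.0)

    def test_duplicated_column_with_missingness(self):
        x = np.array([0, 1, 2, 1, 0, 2, 1, 0, 1, 2, 0, 1, 2, 1, 0, 2, 1, 0, 1, 2])
        y = x.copy()
        y[3] = MISSING  # 5% missing: identical observed values
        assert ld_r2(x, y) == pytest.approx(1.0)

    def test_independent_columns_low_r2(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(40):
            x = rng.binomial(2, 0.3, 500)
            y = rng.binomial(2, 0.3, 500)
            hits += ld_r2(x, y) < 0.05
        assert hits / 40 >= 0.9

    def test_too_few_complete_pairs_errors(self):
        with pytest.raises(ValueError):
            ld_r2(np.array([0, MISSING]), np.array([MISSING, 1]))

    def test_monomorphic_is_zero(self):
        assert ld_r2(np.array([1, 1, 1]), np.array([0, 1, 2])) == 0.0


def _recs(n, chrom="1"):
    return [
        VariantRecord(f"v{j}", "ACAN", chrom, 100 + j, "A", "T", "missense")
        for j in range(n)
    ]


class TestLdPrune:
    def test_perfectly_correlated_pair_keeps_one(self):
        rng = np.random.default_rng(2)
        a = rng.binomial(2, 0.4, 100).astype(np.int8)
        m = make_matrix(np.column_stack([a, a]))
        kept = ld_prune(m, _recs(2))
        assert len(kept) == 1

    def test_independent_variants_all_kept(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, (200, 10)).astype(np.int8)
        m = make_matrix(d)
        kept = ld_prune(m, _recs(10))
        assert len(kept) == 10

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        base = rng.binomial(2, 0.4, (150, 6))
        dup = np.column_stack([base, base[:, :3]])  # 3 duplicated columns
        m = make_matrix(dup.astype(np.int8))
        kept1 = ld_prune(m, _recs(9))
        m2 = m.subset_variants(kept1)
        kept2 = ld_prune(m2, [r for r in _recs(9) if r.variant_id in set(kept1)])
        assert kept1 == kept2

    def test_m_effective_monotone_in_r2_max(self, small_panel):
        c = simulate_cohort(
            CohortSimConfig(panel=small_panel, n_cases=60, n_controls=60, seed=6)
        )
        ms = []
        for r2max in (0.8, 0.5, 0.2, 0.05):
            _, rep = run_qc(c.genotypes, c.variants, ld_r2_max=r2max)
            ms.append(rep.m_effective)
        assert ms == sorted(ms, reverse=True)


class TestPca:
    def test_two_subpopulations_separate_on_pc1(self):
        rng = np.random.default_rng(5)
        n, m = 120, 150
        freqs_a = rng.uniform(0.1, 0.4, m)
        freqs_b = np.clip(freqs_a + rng.choice([-0.35, 0.35], m), 0.02, 0.95)
        d = np.vstack(
            [rng.binomial(2, freqs_a, (n // 2, m)), rng.binomial(2, freqs_b, (n // 2, m))]
        ).astype(np.int8)
        mat = make_matrix(d)
        scores = pca_covariates(mat, k=2)
        g1, g2 = scores[: n // 2, 0], scores[n // 2 :, 0]
        pooled_sd = np.sqrt((g1.var() + g2.var()) / 2)
        assert abs(g1.mean() - g2.mean()) > 2 * pooled_sd

    def test_k_zero_empty(self):
        m = make_matrix([[0, 1], [1, 2], [2, 0]])
        assert pca_covariates(m, 0).shape == (3, 0)

    def test_k_above_rank_errors(self):
        m = make_matrix([[0, 1], [1, 2], [2, 0]])
        with pytest.raises(ValueError, match="rank"):
            pca_covariates(m, 5)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.3, (30, 40)).astype(np.int8)
        m = make_matrix(d)
        perm = rng.permutation(30)
        m2 = m.subset_samples([m.sample_ids[i] for i in perm])
        s1 = pca_covariates(m, 2)
        s2 = pca_covariates(m2, 2)
        np.testing.assert_allclose(s1[perm], s2, atol=1e-8)


class TestRunQc:
    def test_counts_reconcile_and_reasons_exclusive(self, small_panel):
        c = simulate_cohort(
            CohortSimConfig(
                panel=small_panel, n_cases=50, n_controls=50, seed=10, missing_rate=0.1
            )
        )
        m, rep = run_qc(c.genotypes, c.variants)
        assert set(rep.samples_removed) | set(m.sample_ids) == set(
            c.genotypes.sample_ids
        )
        assert not (set(rep.samples_removed) & set(m.sample_ids))
        kept = set(rep.kept_variants)
        assert kept <= set(m.variant_ids)
        # m_effective is exactly the pruned-in, common, retained set
        assert rep.m_effective == len(kept)
        assert not (kept & set(rep.pruned_out))
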