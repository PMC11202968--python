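"""Screening-statistics tests against independently coded oracles."""

from itertools import combinations

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from haplobiva.genomics_io import MISSING, GenotypeMatrix, VariantInfo
from haplobiva.popgen import (
    UndefinedStatisticError, compute_fst, compute_ld, compute_maf,
    detect_blocks, tajimas_d,
)
from haplobiva.synthetic_data import generate_neutral_region

# ---------------------------------------------------------------------------
# Oracles (deliberately naive, loop-based, separate from the implementation)


def tajima_oracle(m):
    """Exhaustive-pair Tajima's D: pi from all C(n,2) sequence pairs."""
    m = np.asarray(m)
    n = m.shape[0]
    pairs = list(combinations(range(n), 2))
    pi = sum(int(np.sum(m[i] != m[j])) for i, j in pairs) / len(pairs)
    counts = m.sum(axis=0)
    s = int(np.sum((counts > 0) & (counts < n)))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1, e2 = c1 / a1, c2 / (a1 ** 2 + a2)
    if s == 0:
        return pi, s, None
    return pi, s, (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def wc_fst_oracle(p1, p2, h1, h2, n1, n2):
    """Loop-free transliteration of the published two-population theta-hat."""
    r = 2
    n = [n1, n2]
    p = [p1, p2]
    h = [h1, h2]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def ld_likelihood_maximizer(d_a, d_b):
    """Maximize the two-locus genotype likelihood over p_ab by bounded search,
    independent of the EM iteration."""
    d_a, d_b = np.asarray(d_a), np.asarray(d_b)
    n = d_a.size
    p_a = d_a.sum() / (2 * n)
    p_b = d_b.sum() / (2 * n)

    def negloglik(p_ab):
        f = {
            (1, 1): p_ab, (1, 0): p_a - p_ab,
            (0, 1): p_b - p_ab, (0, 0): 1 - p_a - p_b + p_ab,
        }
        if min(f.values()) < 0:
            return np.inf
        ll = 0.0
        for da, db in zip(d_a, d_b):
            prob = 0.0
            for h1 in f:
                for h2 in f:
                    if h1[0] + h2[0] == da and h1[1] + h2[1] == db:
                        prob += f[h1] * f[h2]
            if prob <= 0:
                return np.inf
            ll += np.log(prob)
        return -ll

    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    res = minimize_scalar(
        negloglik, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    return res.x


# ---------------------------------------------------------------------------


class TestMaf:
    def test_all_heterozygous_gives_half(self):
        assert compute_maf([1, 1]) == 0.5

    def test_monomorphic_is_zero(self):
        assert compute_maf([0, 0, 0]) == 0.0
        assert compute_maf([2, 2]) == 0.0

    def test_direct_allele_counting(self, rng):
        # 46 diploids, 40 alt alleles of 92
        d = np.zeros(46, dtype=int)
        d[:20] = 2
        assert compute_maf(rng.permutation(d)) == pytest.approx(40 / 92, abs=5e-5)

    def test_missing_excluded_from_both_counts(self):
        assert compute_maf([1, 1, MISSING]) == 0.5

    def test_all_missing_raises(self):
        with pytest.raises(UndefinedStatisticError):
            compute_maf([MISSING, MISSING])


class TestFst:
    @staticmethod
    def _cohort(p1, p2, n1, n2, rng):
        d = np.concatenate([rng.binomial(2, p1, n1), rng.binomial(2, p2, n2)])
        g = np.array(["A"] * n1 + ["B"] * n2)
        return d, g

    def test_no_divergence_limits(self):
        d = np.array([0, 1, 2, 1, 0, 1, 2, 1])
        g = np.array(["A"] * 4 + ["B"] * 4)
        assert compute_fst(d, g, "hudson").fst == pytest.approx(0.0, abs=1e-12)
        assert abs(compute_fst(d, g, "weir_cockerham").fst) < 0.25

    def test_fixed_difference_is_one(self):
        d = np.array([2, 2, 2, 0, 0, 0])
        g = np.array(["A"] * 3 + ["B"] * 3)
        assert compute_fst(d, g, "hudson").fst == pytest.approx(1.0)
        assert compute_fst(d, g, "weir_cockerham").fst == pytest.approx(1.0, abs=0.05)

    def test_weir_cockerham_matches_transliterated_formula(self, rng):
        d, g = self._cohort(0.7, 0.1, 50, 50, rng)
        res = compute_fst(d, g, "weir_cockerham")
        dA, dB = d[:50], d[50:]
        expected = wc_fst_oracle(
            dA.mean() / 2, dB.mean() / 2,
            np.mean(dA == 1), np.mean(dB == 1), 50, 50,
        )
        assert res.fst == pytest.approx(expected, abs=1e-12)

    def test_hudson_closed_form(self, rng):
        d, g = self._cohort(0.7, 0.1, 50, 50, rng)
        res = compute_fst(d, g, "hudson")
        p1, p2 = d[:50].mean() / 2, d[50:].mean() / 2
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        assert res.fst == pytest.approx((p1 - p2) ** 2 / hb, abs=1e-12)

    def test_null_mean_near_zero(self, rng):
        # no structure: mean WC Fst over 1000 simulated sites ~ 0
        vals = []
        for _ in range(1000):
            p = rng.uniform(0.1, 0.9)
            d, g = self._cohort(p, p, 40, 40, rng)
            try:
                vals.append(compute_fst(d, g, "weir_cockerham").fst)
            except UndefinedStatisticError:
                continue
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_group_all_missing_is_undefined(self):
        d = np.array([1, 1, MISSING, MISSING])
        g = np.array(["A", "A", "B", "B"])
        with pytest.raises(UndefinedStatisticError):
            compute_fst(d, g)


class TestLD:
    def test_perfect_correlation(self):
        d = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        ld = compute_ld(d, d)
        assert ld.d_prime == pytest.approx(1.0, abs=1e-9)
        assert ld.r2 == pytest.approx(1.0, abs=1e-9)

    def test_independent_sites_near_zero(self, rng):
        a = rng.binomial(2, 0.5, 4000)
        b = rng.binomial(2, 0.3, 4000)
        ld = compute_ld(a, b)
        assert ld.r2 < 0.01

    def test_em_exact_without_double_heterozygotes(self, rng):
        # build 20 genotypes from known phased haplotypes such that nobody is
        # het at both sites; then haplotype counts are directly observable
        hap_pool = [(1, 1)] * 12 + [(0, 0)] * 20 + [(1, 0)] * 8
        pairs = []
        while len(pairs) < 20:
            i, j = rng.integers(len(hap_pool), size=2)
            h1, h2 = hap_pool[i], hap_pool[j]
            da, db = h1[0] + h2[0], h1[1] + h2[1]
            if (da, db) != (1, 1):
                pairs.append((h1, h2))
        d_a = np.array([h1[0] + h2[0] for h1, h2 in pairs])
        d_b = np.array([h1[1] + h2[1] for h1, h2 in pairs])
        true_p_ab = sum((h == (1, 1)) for p in pairs for h in p) / 40
        ld = compute_ld(d_a, d_b)
        assert ld.p_ab == pytest.approx(true_p_ab, abs=1e-6)

    def test_em_matches_likelihood_maximizer(self, rng):
        for _ in range(5):
            d_a = rng.binomial(2, 0.45, 20)
            d_b = np.where(
                rng.random(20) < 0.7, d_a, rng.binomial(2, 0.45, 20)
            )  # correlated with ambiguity
            if len(np.unique(d_a)) == 1 or len(np.unique(d_b)) == 1:
                continue
            ld = compute_ld(d_a, d_b)
            assert ld.p_ab == pytest.approx(
                ld_likelihood_maximizer(d_a, d_b), abs=1e-5
            )

    def test_r2_bounded_by_d_prime(self, rng):
        for _ in range(50):
            a = rng.binomial(2, rng.uniform(0.1, 0.9), 60)
            b = rng.binomial(2, rng.uniform(0.1, 0.9), 60)
            try:
                ld = compute_ld(a, b)
            except UndefinedStatisticError:
                continue
            assert ld.r2 <= ld.d_prime + 1e-9

    def test_monomorphic_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            compute_ld([0, 0, 0, 0], [0, 1, 2, 1])


def _matrix_from_dosages(dosages, positions=None):
    dosages = np.asarray(dosages)
    n_var = dosages.shape[1]
    positions = positions or [100 * (j + 1) for j in range(n_var)]
    variants = [
        VariantInfo("17", positions[j], f"rs{j}", "A", "G") for j in range(n_var)
    ]
    return GenotypeMatrix(
        variants, [f"S{i}" for i in range(dosages.shape[0])], dosages
    )


class TestDetectBlocks:
    @staticmethod
    def _two_class(n, n_sites, freq, rng):
        """Dosage matrix from two haplotype classes differing at all sites."""
        hap = rng.binomial(1, freq, size=(n, 2))
        return np.repeat(hap.sum(axis=1)[:, None], n_sites, axis=1)

    def test_mutually_correlated_run_is_one_block(self, rng):
        m = _matrix_from_dosages(self._two_class(50, 5, 0.5, rng))
        blocks = detect_blocks(m)
        assert len(blocks) == 1 and blocks[0].n_snps == 5

    def test_recovers_planted_block_among_unlinked_flankers(self, rng):
        core = self._two_class(80, 5, 0.4, rng)
        left = rng.binomial(2, 0.5, size=(80, 2))
        right = rng.binomial(2, 0.5, size=(80, 1))
        m = _matrix_from_dosages(np.hstack([left, core, right]))
        blocks = detect_blocks(m)
        assert len(blocks) == 1
        assert [v.id for v in blocks[0].variants] == ["rs2", "rs3", "rs4", "rs5", "rs6"]
        assert blocks[0].interval.start == 300 and blocks[0].interval.end == 700

    def test_no_blocks_when_ld_weak(self, rng):
        m = _matrix_from_dosages(rng.binomial(2, 0.5, size=(60, 6)))
        assert detect_blocks(m) == []

    def test_invariant_to_sample_ordering(self, rng):
        core = self._two_class(60, 4, 0.5, rng)
        noise = rng.binomial(2, 0.4, size=(60, 2))
        dosages = np.hstack([core, noise])
        m1 = _matrix_from_dosages(dosages)
        perm = rng.permutation(60)
        m2 = _matrix_from_dosages(dosages[perm])
        b1 = detect_blocks(m1)
        b2 = detect_blocks(m2)
        assert [[v.id for v in b.variants] for b in b1] == [
            [v.id for v in b.variants] for b in b2
        ]


class TestTajima:
    def test_toy_haplotypes_hand_countable(self):
        # sequences AAA, AAT, GAT, GAT over 3 sites -> 0/1 coding per site
        m = np.array([[0, 0, 0], [0, 0, 1], [1, 0, 1], [1, 0, 1]])
        res = tajimas_d(m)
        assert res.s == 2
        assert res.pi == pytest.approx(7 / 6)
        _, _, d_expected = tajima_oracle(m)
        assert res.d == pytest.approx(d_expected, abs=1e-12)

    def test_balanced_two_class_positive(self):
        m = generate_neutral_region(40, 20, "balanced_two_class", seed=5)
        assert tajimas_d(m).d > 0

    def test_singleton_excess_negative(self):
        m = generate_neutral_region(10, 12, "singleton_excess", seed=5)
        assert tajimas_d(m).d < 0

    def test_matches_exhaustive_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 9))
            n_sites = int(rng.integers(1, 11))
            m = rng.binomial(1, rng.uniform(0.1, 0.9), size=(n, n_sites))
            pi, s, d = tajima_oracle(m)
            res = tajimas_d(m)
            assert res.s == s
            assert res.pi == pytest.approx(pi, abs=1e-9)
            if d is None:
                assert res.d is None
            else:
                assert res.d == pytest.approx(d, abs=1e-9)

    def test_genotype_input_matches_expanded_haplotypes_without_phase(self):
        # per-site frequency pi is phase-free, so dosages = summed haplotypes
        m = np.array([[0, 1, 1], [1, 0, 1], [0, 0, 0], [1, 1, 1],
                      [0, 1, 0], [1, 1, 0]])
        geno = m[0::2] + m[1::2]
        hap_res = tajimas_d(m, input_type="haplotypes")
        gen_res = tajimas_d(geno, input_type="genotypes")
        assert gen_res.pi == pytest.approx(hap_res.pi, abs=1e-12)
        assert gen_res.d == pytest.approx(hap_res.d, abs=1e-12)

    def test_no_segregating_sites_flagged_undefined(self):
        res = tajimas_d(np.zeros((6, 4), dtype=int))
        assert res.s == 0 and res.d is None
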