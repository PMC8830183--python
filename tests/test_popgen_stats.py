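"""Allele-frequency statistics against exact-arithmetic oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats
from hypothesis import given, settings
from hypothesis import strategies as st

from panelpatterns.popgen_stats import (
    ReferenceFrequencyTable,
    af_fisher_test,
    allele_frequency,
    benjamini_hochberg,
    genotypic_r2,
    group_af_screen,
    hwe_exact_test,
)
from panelpatterns.synthetic_fixtures import SyntheticCohortSpec, simulate_cohort
from panelpatterns.variant_matrix import VariantKey

from conftest import make_matrix


# ---------------------------------------------------------------------- oracles

def fisher_oracle(a, r1, r2, c1):
    """Exact-rational two-sided Fisher p for cell a with margins (r1, r2, c1)."""
    denom = comb(r1 + r2, c1)
    probs = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
             for k in range(max(0, c1 - r2), min(r1, c1) + 1)}
    bound = probs[a] * Fraction(10_000_001, 10_000_000)  # R-style tie tolerance
    return float(sum(p for p in probs.values() if p <= bound))


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact-rational conditional HWE p by enumerating heterozygote counts."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    if na == 0 or nb == 0:
        return 1.0
    rare = min(na, nb)

    def prob(h):
        i, j = (rare - h) // 2, (2 * n - rare - h) // 2
        from math import factorial
        return Fraction(factorial(n) * 2 ** h, factorial(i) * factorial(h)
                        * factorial(j)) \
            * Fraction(factorial(na) * factorial(nb), factorial(2 * n))

    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


def bh_oracle(pvals):
    """Step-up BH applied literally from its definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj[i] = running
    return adj


# ------------------------------------------------------------------ unit tests

class TestAlleleFrequency:
    @pytest.mark.parametrize("row,n,expected", [
        ([0] * 10, 10, (0, 20, 0.0)),
        ([2, 0], 2, (2, 4, 0.5)),
        ([1, 1, 1, 2, 0, 0, 0, 0, 0, 0], 10, (5, 20, 0.25)),
    ])
    def test_counting(self, row, n, expected):
        assert allele_frequency(row, n) == expected

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            allele_frequency([0, 3], 2)


class TestFisher:
    def test_zero_margin_gives_p_one(self):
        _, p = af_fisher_test(0, 20, 0, 1000)
        assert p == 1.0

    def test_matches_enumeration_oracle(self):
        _, p = af_fisher_test(3, 20, 10, 200)
        assert p == pytest.approx(fisher_oracle(3, 20, 200, 13), rel=1e-10)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            can, ran = int(rng.integers(1, 40)), int(rng.integers(1, 40))
            ca = int(rng.integers(0, can + 1))
            ra = int(rng.integers(0, ran + 1))
            if ca + ra == 0 or (can - ca) + (ran - ra) == 0:
                continue  # transposed table would have an empty row
            _, p1 = af_fisher_test(ca, can, ra, ran)
            # transposed table: rows become (alt, ref) across populations
            _, p2 = af_fisher_test(ca, ca + ra, can - ca, (can - ca) + (ran - ra))
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            can, ran = int(rng.integers(2, 60)), int(rng.integers(2, 3000))
            ca = int(rng.integers(0, can + 1))
            ra = int(rng.integers(0, ran + 1))
            _, p = af_fisher_test(ca, can, ra, ran)
            p_ref = stats.fisher_exact([[ca, can - ca], [ra, ran - ra]])[1]
            assert p == pytest.approx(p_ref, rel=1e-8)

    def test_haldane_anscombe_odds_ratio_on_zero_cell(self):
        odds, _ = af_fisher_test(0, 10, 5, 100)
        assert odds == pytest.approx((0.5 * 95.5) / (10.5 * 5.5))

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            af_fisher_test(5, 4, 0, 10)
        with pytest.raises(ValueError):
            af_fisher_test(0, 0, 1, 10)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.04])[0] == pytest.approx(0.04)

    def test_hand_worked_example(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(benjamini_hochberg([1.0] * 5), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_step_up_oracle_and_monotone(self, pvals):
        adj = benjamini_hochberg(pvals)
        np.testing.assert_allclose(adj, bh_oracle(pvals), atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestHwe:
    def test_monomorphic_flagged_with_p_one(self):
        res = hwe_exact_test(10, 0, 0)
        assert res.p == 1.0 and res.monomorphic

    def test_matches_enumeration_oracle(self):
        res = hwe_exact_test(3, 5, 2)
        assert res.p == pytest.approx(hwe_oracle(3, 5, 2), rel=1e-10)

    def test_opposite_tails_all_het_vs_no_het(self):
        # same allele counts (10 ref, 10 alt), opposite extremes
        p_all_het = hwe_exact_test(0, 10, 0).p
        p_no_het = hwe_exact_test(5, 0, 5).p
        assert p_all_het == pytest.approx(hwe_oracle(0, 10, 0), rel=1e-10)
        assert p_no_het == pytest.approx(hwe_oracle(5, 0, 5), rel=1e-10)
        assert p_no_het < p_all_het  # no-het is the rarer configuration

    def test_asymptotic_agreement_with_chi_square(self):
        """Exact p approaches the 1-df chi-square p for large equilibrium samples."""
        rng = np.random.default_rng(8)
        n = 10_000
        for af in (0.2, 0.35):
            g = rng.binomial(2, af, size=n)
            counts = [int((g == i).sum()) for i in (0, 1, 2)]
            res = hwe_exact_test(*counts)
            n_alt = counts[1] + 2 * counts[2]
            q = n_alt / (2 * n)
            expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q]) * n
            chi2 = float(((np.array(counts) - expected) ** 2 / expected).sum())
            p_chi = float(stats.chi2.sf(chi2, df=1))
            assert res.p == pytest.approx(p_chi, abs=0.02)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestGenotypicR2:
    def test_identical_rows_give_one(self):
        assert genotypic_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_perfect_negative_correlation_gives_one(self):
        assert genotypic_r2([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_matches_pearson_formula(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 3, 30)
        y = rng.integers(0, 3, 30)
        xc, yc = x - x.mean(), y - y.mean()
        r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert genotypic_r2(x, y) == pytest.approx(r * r, rel=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            genotypic_r2([1, 1, 1], [0, 1, 2])

    def test_planted_ld_block_rows_fully_correlated(self, default_cohort):
        m = default_cohort.matrix
        labels = default_cohort.truth["ld_block"]["variants"]
        rows = [m.values[m.index_of(VariantKey.from_label(l))] for l in labels]
        for other in rows[1:]:
            assert genotypic_r2(rows[0], other) == pytest.approx(1.0)


class TestGroupScreen:
    def _reference(self, keys, af=0.01, an=10_000):
        ref = ReferenceFrequencyTable()
        for k in keys:
            ref.add(k, int(af * an), an)
        return ref

    def test_constant_design_mean_count(self):
        # 4 samples each carrying exactly 7 variants
        m = make_matrix(np.ones((7, 4), dtype=np.int8), "ternary")
        labels = {s: "g" for s in m.samples}
        _, summ = group_af_screen(m, labels, self._reference(m.variants))
        assert summ["g"].mean_variants_per_patient == 7.0
        assert summ["g"].n_unique_variants == 7

    def test_planted_large_shift_is_discovered(self):
        # cohort AF 0.5 in 40 samples vs reference 0.001: survives BH easily
        rng = np.random.default_rng(21)
        values = rng.binomial(2, 0.01, size=(200, 40)).astype(np.int8)
        values[0] = rng.binomial(2, 0.5, size=40)
        keep = values.any(axis=1)
        m = make_matrix(values[keep], "ternary")
        ref = ReferenceFrequencyTable()
        for i, k in enumerate(m.variants):
            ref.add(k, 10, 10_000)
        labels = {s: "g" for s in m.samples}
        results, summ = group_af_screen(m, labels, ref, alpha=0.05)
        planted = m.variants[0]
        hit = next(r for r in results if r.variant == planted)
        assert hit.p_adj < 0.05
        assert summ["g"].n_significant >= 1

    def test_not_in_reference_flagged_not_dropped(self):
        m = make_matrix([[1, 1], [0, 1]], "ternary")
        ref = self._reference([m.variants[0]])
        results, _ = group_af_screen(m, {s: "g" for s in m.samples}, ref)
        flags = {r.variant: r.not_in_reference for r in results}
        assert flags[m.variants[0]] is False
        assert flags[m.variants[1]] is True

    def test_absent_variants_not_tested_in_group(self):
        values = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.int8)
        m = make_matrix(values, "ternary")
        labels = dict(zip(m.samples, ["a", "a", "b", "b"]))
        results, summ = group_af_screen(m, labels, self._reference(m.variants))
        tested = {(r.group, r.variant.pos) for r in results}
        assert tested == {("a", 100), ("b", 110)}
        assert summ["a"].n_unique_variants == 1

    def test_invariant_to_sample_and_row_permutation(self):
        rng = np.random.default_rng(23)
        values = rng.integers(0, 3, size=(12, 8)).astype(np.int8)
        values[~values.any(axis=1), 0] = 1
        m = make_matrix(values, "ternary")
        labels = {s: ("a" if i % 2 else "b") for i, s in enumerate(m.samples)}
        ref = self._reference(m.variants)
        res1, summ1 = group_af_screen(m, labels, ref)
        perm = rng.permutation(len(m.samples))
        m2 = m.subset_samples([m.samples[i] for i in perm])
        rperm = rng.permutation(m.shape[0])
        m2 = type(m2)([m2.variants[i] for i in rperm], m2.samples,
                      m2.values[rperm], "ternary")
        res2, summ2 = group_af_screen(m2, labels, ref)
        key = lambda r: (r.group, r.variant.sort_key())
        for a, b in zip(sorted(res1, key=key), sorted(res2, key=key)):
            assert a.variant == b.variant and a.p == b.p and a.p_adj == b.p_adj
        assert {g: s.mean_variants_per_patient for g, s in summ1.items()} == \
            {g: s.mean_variants_per_patient for g, s in summ2.items()}

    def test_unlabelled_sample_rejected(self):
        m = make_matrix([[1, 1]], "ternary")
        with pytest.raises(ValueError):
            group_af_screen(m, {m.samples[0]: "g"}, self._reference(m.variants))


class TestReferenceTable:
    def test_tsv_round_trip_and_rsid_lookup(self, tmp_path):
        ref = ReferenceFrequencyTable()
        k1 = VariantKey("1", 100, "A", "G", rsid="rs7")
        k2 = VariantKey("2", 200, "C", "T")
        ref.add(k1, 5, 1000)
        ref.add(k2, 0, 500)
        path = tmp_path / "ref.tsv"
        ref.to_tsv(path)
        back = ReferenceFrequencyTable.from_tsv(path)
        assert back.lookup(k1) == (5, 1000)
        assert back.lookup(k2) == (0, 500)
        # rsid fallback when positions differ
        probe = VariantKey("1", 999, "A", "G", rsid="rs7")
        assert back.lookup(probe) == (5, 1000)

    def test_invalid_counts_rejected(self):
        ref = ReferenceFrequencyTable()
        with pytest.raises(ValueError):
            ref.add(VariantKey("1", 1, "A", "G"), 5, 4)
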