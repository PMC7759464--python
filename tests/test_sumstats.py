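"""Statistic correctness against hand-derived values and brute-force oracles."""

import numpy as np
import pytest
from oracles import (
    brute_dxy,
    brute_fay_wu_h,
    brute_garud,
    brute_gmin,
    brute_haf,
    brute_hudson_fst,
    brute_pi,
    brute_ss_h12,
    brute_tajimas_d,
    brute_watterson,
)

from conftest import random_matrix, random_two_pop_matrix
from sweepscan import sumstats as ss
from sweepscan.popdata import HaplotypeMatrix, PopulationPair


def mat(rows, pops=None, polarized=True):
    rows = np.asarray(rows, dtype=np.int8)
    n_hap, n_sites = rows.shape
    if pops is None:
        pops = ["A"] * (n_hap // 2)
    return HaplotypeMatrix(
        rows,
        np.arange(n_sites, dtype=np.int64),
        "chr1",
        [f"s{i}" for i in range(n_hap // 2)],
        np.asarray(pops),
        np.full(n_sites, polarized, dtype=bool),
    )


# ---------------------------------------------------------------------------
# hand-derived example values


class TestExamples:
    def test_pi_single_pair(self):
        h = mat([[0, 0], [0, 1]])
        assert ss.nucleotide_diversity(h, None, 2) == pytest.approx(0.5)

    def test_pi_identical_haplotypes_is_zero(self):
        h = mat(np.zeros((4, 3)))
        assert ss.nucleotide_diversity(h, None, 3) == 0.0

    def test_pi_four_haplotypes_derived_two(self):
        # 2*2*2/(4*3) = 2/3 per accessible bp
        h = mat([[1], [1], [0], [0]])
        assert ss.nucleotide_diversity(h, None, 1) == pytest.approx(2 / 3)

    def test_tajimas_d_zero_numerator_identity(self):
        # intermediate-frequency site in n=4: pi_total = S/a1 exactly when
        # 2*2*2/(4*3) * a1(4) == 1, checked against the textbook oracle
        d = ss.tajimas_d(mat([[0], [1], [1], [0]]))
        assert d == pytest.approx(brute_tajimas_d(np.array([[0], [1], [1], [0]])))

    def test_tajimas_d_all_singletons_negative(self, rng):
        alleles = np.zeros((10, 5), dtype=np.int8)
        for j in range(5):
            alleles[j, j] = 1
        h = mat(alleles)
        d = ss.tajimas_d(h)
        assert d < 0
        assert d == pytest.approx(brute_tajimas_d(alleles), abs=1e-9)

    def test_fay_wu_h_n2_is_zero(self):
        # theta_pi and theta_H coincide identically at n = 2
        assert ss.fay_wu_h(mat([[0], [1]])) == pytest.approx(0.0)

    def test_fay_wu_h_high_frequency_derived(self):
        # n=4, one site with derived count 3: theta_pi=0.5, theta_H=1.5
        h = mat([[1], [1], [1], [0]])
        assert ss.fay_wu_h(h) == pytest.approx(-1.0)

    def test_fay_wu_h_singletons_positive(self):
        alleles = np.zeros((6, 4), dtype=np.int8)
        for j in range(4):
            alleles[j, j] = 1
        assert ss.fay_wu_h(mat(alleles)) > 0

    def test_garud_two_equal_classes(self):
        h = mat([[0, 0], [0, 0], [1, 1], [1, 1]])
        h1, h12, h2h1 = ss.garud_h(h)
        assert (h1, h12, h2h1) == pytest.approx((0.5, 1.0, 0.5))

    def test_garud_monomorphic(self):
        h = mat(np.zeros((6, 0)))
        assert ss.garud_h(h) == pytest.approx((1.0, 1.0, 0.0))

    def test_garud_three_classes(self):
        # frequencies 0.6 / 0.3 / 0.1 over 10 haplotypes
        rows = [[0, 0]] * 6 + [[1, 0]] * 3 + [[1, 1]]
        h1, h12, h2h1 = ss.garud_h(mat(rows))
        assert h1 == pytest.approx(0.46)
        assert h12 == pytest.approx(0.82)
        assert h2h1 == pytest.approx((0.46 - 0.36) / 0.46)

    def test_haf_no_derived(self):
        assert np.isnan(ss.haf_score(mat(np.zeros((4, 0)))))  # no polarized sites
        h2 = mat([[0], [0], [1], [0]])
        assert ss.haf_score(h2) == pytest.approx(1 / 4)

    def test_haf_two_carriers(self):
        # one site, two carriers among four haplotypes: scores (2,2,0,0)
        h = mat([[1], [1], [0], [0]])
        assert ss.haf_score(h) == pytest.approx((2 + 2 + 0 + 0) / 4)

    def test_haf_duplicating_columns_doubles_score(self, rng):
        m = random_matrix(rng, 8, 10)
        doubled = mat(np.concatenate([m.alleles, m.alleles], axis=1))
        assert ss.haf_score(doubled) == pytest.approx(2 * brute_haf(m.alleles))

    def test_fst_fixed_difference(self):
        h, pair = _two_pop([[1, 1], [1, 1]], [[0, 0], [0, 0]])
        assert ss.hudson_fst(h, None, pair) == pytest.approx(1.0)

    def test_fst_site_values_balanced(self):
        # p1 = p2 = 0.5 with n1 = n2 = 10 haplotypes
        col_a = np.array([[1]] * 5 + [[0]] * 5, dtype=np.int8)
        col_b = np.array([[1]] * 5 + [[0]] * 5, dtype=np.int8)
        h, pair = _two_pop(col_a, col_b)
        num, den, _ = ss.hudson_fst_components(h, pair)
        assert num[0] == pytest.approx(-0.05555555555)
        assert den[0] == pytest.approx(0.5)
        assert num[0] / den[0] == pytest.approx(-0.111111111)

    def test_dxy_fixed_difference(self):
        h, pair = _two_pop([[1], [1]], [[0], [0]])
        assert ss.dxy(h, None, pair, 1) == pytest.approx(1.0)

    def test_dxy_cross_pair_enumeration(self):
        # 2 of 4 cross pairs differ at the single site; 10 accessible bp
        h, pair = _two_pop([[0], [1]], [[1], [1]])
        a = h.alleles[h.rows_for_pop("A")]
        b = h.alleles[h.rows_for_pop("B")]
        assert brute_dxy(a, b, 10) == pytest.approx(0.05)
        assert ss.dxy(h, None, pair, 10) == pytest.approx(brute_dxy(a, b, 10))

    def test_gmin_all_equal_distances(self):
        h, pair = _two_pop([[1, 0], [1, 0]], [[0, 1], [0, 1]])
        assert ss.gmin(h, None, pair) == pytest.approx(1.0)

    def test_gmin_identical_cross_pair(self):
        h, pair = _two_pop([[0, 0], [1, 1]], [[0, 0], [1, 0]])
        a = h.alleles[h.rows_for_pop("A")]
        b = h.alleles[h.rows_for_pop("B")]
        expected = brute_gmin(a, b)
        assert expected < 1
        assert ss.gmin(h, None, pair) == pytest.approx(expected)

    def test_gmin_zero_distance_pair(self):
        # cross distances {0, 2, 2, 4}: min/mean = 0/2 = 0
        h, pair = _two_pop(
            [[0, 0, 0, 0], [1, 1, 1, 1]], [[0, 0, 0, 0], [0, 0, 1, 1]]
        )
        a = h.alleles[h.rows_for_pop("A")]
        b = h.alleles[h.rows_for_pop("B")]
        assert sorted(int(np.sum(x != y)) for x in a for y in b) == [0, 2, 2, 4]
        assert ss.gmin(h, None, pair) == pytest.approx(0.0)

    def test_ssh12_shared_fixed_haplotype(self):
        h, pair = _two_pop([[1, 1], [1, 1]], [[1, 1], [1, 1]])
        assert ss.ss_h12(h, None, pair) == pytest.approx(1.0)

    def test_ssh12_private_fixed_haplotypes(self):
        h, pair = _two_pop([[1, 1], [1, 1]], [[0, 0], [0, 0]])
        v = ss.ss_h12(h, None, pair)
        assert v < 0
        a = h.alleles[h.rows_for_pop("A")]
        b = h.alleles[h.rows_for_pop("B")]
        assert v == pytest.approx(brute_ss_h12(a, b))

    def test_watterson_simple(self):
        h = mat([[0] * 7, [1] * 7])
        assert ss.watterson_theta(h, None, 1000) == pytest.approx(0.007)
        assert ss.watterson_theta(mat(np.zeros((4, 0))), None, 100) == 0.0


def _two_pop(rows_a, rows_b):
    rows_a = np.asarray(rows_a, dtype=np.int8)
    rows_b = np.asarray(rows_b, dtype=np.int8)
    alleles = np.concatenate([rows_a, rows_b], axis=0)
    n_a, n_b = rows_a.shape[0], rows_b.shape[0]
    pops = ["A"] * (n_a // 2) + ["B"] * (n_b // 2)
    h = mat(alleles, pops=pops)
    return h, PopulationPair("A", "B", n_a, n_b)


# ---------------------------------------------------------------------------
# brute-force oracle agreement on random matrices


def test_all_statistics_agree_with_brute_force(rng):
    """Every statistic matches an independent enumeration to 1e-9 on random
    two-population matrices (n <= 20 haplotypes, <= 50 sites)."""
    for _ in range(200):
        n_a = 2 * int(rng.integers(2, 6))
        n_b = 2 * int(rng.integers(2, 6))
        n_sites = int(rng.integers(2, 51))
        hap, pair = random_two_pop_matrix(rng, n_a // 2, n_b // 2, n_sites)
        a = hap.alleles[hap.rows_for_pop("A")]
        b = hap.alleles[hap.rows_for_pop("B")]
        acc = 1000

        assert ss.nucleotide_diversity(hap.subpop("A"), None, acc) == pytest.approx(
            brute_pi(a, acc), abs=1e-9
        )
        assert ss.watterson_theta(hap.subpop("A"), None, acc) == pytest.approx(
            brute_watterson(a, acc), abs=1e-9
        )
        assert ss.tajimas_d(hap.subpop("A")) == pytest.approx(
            brute_tajimas_d(a), abs=1e-9, nan_ok=True
        )
        assert ss.fay_wu_h(hap.subpop("A")) == pytest.approx(
            brute_fay_wu_h(a), abs=1e-9, nan_ok=True
        )
        got = ss.garud_h(hap.subpop("B"))
        want = brute_garud(b)
        assert got == pytest.approx(want, abs=1e-9)
        assert ss.haf_score(hap.subpop("B")) == pytest.approx(brute_haf(b), abs=1e-9)
        assert ss.hudson_fst(hap, None, pair) == pytest.approx(
            brute_hudson_fst(a, b), abs=1e-9, nan_ok=True
        )
        assert ss.dxy(hap, None, pair, acc) == pytest.approx(
            brute_dxy(a, b, acc), abs=1e-9
        )
        assert ss.gmin(hap, None, pair) == pytest.approx(brute_gmin(a, b), abs=1e-9)
        assert ss.ss_h12(hap, None, pair) == pytest.approx(
            brute_ss_h12(a, b), abs=1e-9
        )


def test_statistics_with_missing_data_match_per_site_enumeration(rng):
    """Frequency-based statistics use observed non-missing counts per site."""
    for _ in range(50):
        hap, pair = random_two_pop_matrix(rng, 4, 4, 20, missing_frac=0.1)
        a = hap.alleles[hap.rows_for_pop("A")]
        b = hap.alleles[hap.rows_for_pop("B")]
        assert ss.nucleotide_diversity(hap.subpop("A"), None, 500) == pytest.approx(
            brute_pi(a, 500), abs=1e-9
        )
        assert ss.dxy(hap, None, pair, 500) == pytest.approx(
            brute_dxy(a, b, 500), abs=1e-9
        )
        assert ss.hudson_fst(hap, None, pair) == pytest.approx(
            brute_hudson_fst(a, b), abs=1e-9, nan_ok=True
        )


# ---------------------------------------------------------------------------
# invariants


def test_haplotype_statistics_ordering_and_invariance(rng):
    """H12 >= H1 >= H2; invariance to row and site permutations."""
    for _ in range(30):
        hap = random_matrix(rng, 12, 15)
        h1, h12, h2h1 = ss.garud_h(hap)
        assert h12 >= h1 - 1e-12
        assert h1 >= h2h1 * h1 - 1e-12  # H1 >= H2
        perm_rows = rng.permutation(hap.n_haplotypes)
        # permute sample pairs only (rows must stay diploid-paired)
        pairs = rng.permutation(hap.n_samples)
        rows = np.repeat(2 * pairs, 2) + np.tile([0, 1], hap.n_samples)
        shuffled = mat(hap.alleles[rows])
        assert ss.garud_h(shuffled) == pytest.approx((h1, h12, h2h1))
        site_perm = rng.permutation(hap.n_sites)
        resited = mat(hap.alleles[:, site_perm])
        assert ss.garud_h(resited) == pytest.approx((h1, h12, h2h1))


def test_polarization_dependence(rng):
    """pi and dxy are invariant to ancestral/derived relabelling; Fay & Wu's
    H and 1-HAF are not (they weight derived alleles)."""
    hap, pair = random_two_pop_matrix(rng, 4, 4, 12)
    flipped = mat(1 - hap.alleles, pops=["A"] * 4 + ["B"] * 4)
    a = hap.subpop("A")
    fa = flipped.subpop("A")
    assert ss.nucleotide_diversity(a, None, 100) == pytest.approx(
        ss.nucleotide_diversity(fa, None, 100)
    )
    assert ss.dxy(hap, None, pair, 100) == pytest.approx(
        ss.dxy(flipped, None, pair, 100)
    )
    # an asymmetric case: one high-frequency derived site
    rows = np.zeros((6, 1), dtype=np.int8)
    rows[:5] = 1
    asym = mat(rows)
    flip = mat(1 - rows)
    assert ss.fay_wu_h(asym) < 0 < ss.fay_wu_h(flip)
    assert ss.haf_score(asym) != pytest.approx(ss.haf_score(flip))


def test_panmictic_split_fst_is_centred_on_zero(rng):
    """Hudson FST between random halves of one population is ~0 on average."""
    hap = random_matrix(rng, 40, 60)
    vals = []
    for _ in range(100):
        pairs = rng.permutation(20)
        pops = np.array(["X"] * 20)
        pops[pairs[:10]] = "Y"
        relabeled = HaplotypeMatrix(
            hap.alleles, hap.positions, hap.chrom, hap.sample_ids, pops, hap.polarized
        )
        pair = PopulationPair("X", "Y", 20, 20)
        vals.append(ss.hudson_fst(relabeled, None, pair))
    assert abs(np.mean(vals)) < 0.01


def test_undefined_values_are_nan_not_zero():
    empty = mat(np.zeros((4, 0)))
    assert np.isnan(ss.tajimas_d(empty))
    assert np.isnan(ss.fay_wu_h(empty))
    # monomorphic across both populations: FST denominator is 0
    h2, pair2 = _two_pop([[1], [1]], [[1], [1]])
    assert np.isnan(ss.hudson_fst(h2, None, pair2))
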