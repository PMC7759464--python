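"""I/O, masking, polarization and coverage-filter behaviour."""

import numpy as np
import pytest

from conftest import random_matrix
from sweepscan import popdata as pd_
from sweepscan.popdata import (
    MISSING,
    GenotypeDepthMatrix,
    HaplotypeMatrix,
    SiteMask,
    apply_mask,
    coverage_filter,
    polarize,
    read_phased_vcf,
    read_popfile,
    write_phased_vcf,
)


def write_vcf(path, lines, samples=("s0", "s1")):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr1,length=100000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for line in lines:
            fh.write(line + "\n")


POP = {"s0": "A", "s1": "A"}


class TestReadVcf:
    def test_phased_biallelic_snps(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf(
            p,
            [
                "chr1\t11\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1",
                "chr1\t21\t.\tC\tG\t.\tPASS\t.\tGT\t0|0\t0|1",
                "chr1\t31\t.\tG\tA\t.\tPASS\t.\tGT\t1|0\t0|0",
            ],
        )
        hap = read_phased_vcf(p, POP)
        assert hap.alleles.shape == (4, 3)
        assert not (hap.alleles == MISSING).any()
        assert hap.positions.tolist() == [10, 20, 30]  # 1-based -> 0-based
        assert hap.alleles[:, 0].tolist() == [0, 1, 1, 1]

    def test_multiallelic_sites_excluded(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf(
            p,
            [
                "chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1",
                "chr1\t20\t.\tA\tT,G\t.\tPASS\t.\tGT\t0|1\t2|1",
                "chr1\t30\t.\tA\tT\t.\tPASS\t.\tGT\t0|0\t0|1",
                "chr1\t40\t.\tA\tAT\t.\tPASS\t.\tGT\t0|0\t0|1",
                "chr1\t50\t.\tA\tT\t.\tPASS\t.\tGT\t1|1\t0|1",
            ],
        )
        hap = read_phased_vcf(p, POP)
        assert hap.n_sites == 3  # tri-allelic site and indel dropped

    def test_missing_genotype_becomes_missing(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf(p, ["chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t./.\t0|1"])
        hap = read_phased_vcf(p, POP)
        assert hap.alleles[:2, 0].tolist() == [MISSING, MISSING]
        assert hap.alleles[2:, 0].tolist() == [0, 1]

    def test_unphased_het_becomes_missing(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf(p, ["chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0|1"])
        hap = read_phased_vcf(p, POP)
        assert hap.alleles[:2, 0].tolist() == [MISSING, MISSING]
        hap2 = read_phased_vcf(p, POP, require_phased=False)
        assert sorted(hap2.alleles[:2, 0].tolist()) == [0, 1]

    def test_sample_absent_from_popfile_is_an_error(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf(p, ["chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t0|1"])
        with pytest.raises(ValueError, match="s1"):
            read_phased_vcf(p, {"s0": "A"})


def test_vcf_round_trip_preserves_genotypes_and_phase(tmp_path, rng):
    hap = random_matrix(rng, 12, 25, span=5000)
    out = tmp_path / "rt.vcf"
    write_phased_vcf(hap, out)
    back = read_phased_vcf(out, {s: "A" for s in hap.sample_ids})
    assert np.array_equal(back.alleles, hap.alleles)
    assert np.array_equal(back.positions, hap.positions)
    assert back.sample_ids == hap.sample_ids


def test_popfile_parsing(tmp_path):
    p = tmp_path / "pops.tsv"
    p.write_text("# comment line\ns0\tA\ns1 B\n\ns2\tB\n")
    assert read_popfile(p) == {"s0": "A", "s1": "B", "s2": "B"}


# ---------------------------------------------------------------------------
# polarization


def outgroup_mat(cols, n_dip=5):
    """Outgroup matrix from per-diploid genotype tuples per site."""
    cols = np.asarray(cols, dtype=np.int8)  # (n_sites, n_dip, 2)
    alleles = cols.transpose(1, 2, 0).reshape(2 * n_dip, -1)
    n_sites = cols.shape[0]
    return HaplotypeMatrix(
        alleles,
        np.arange(n_sites, dtype=np.int64),
        "chr1",
        [f"og{i}" for i in range(n_dip)],
        np.asarray(["OUT"] * n_dip),
        np.zeros(n_sites, bool),
    )


def ingroup_mat(col):
    col = np.asarray(col, dtype=np.int8)[:, None]
    return HaplotypeMatrix(
        col,
        np.array([0], dtype=np.int64),
        "chr1",
        [f"s{i}" for i in range(len(col) // 2)],
        np.asarray(["A"] * (len(col) // 2)),
        np.zeros(1, bool),
    )


class TestPolarize:
    def test_outgroup_monomorphic_ref_polarizes(self):
        ing = ingroup_mat([0, 1, 1, 0])
        og = outgroup_mat([[(0, 0)] * 5])
        out = polarize(ing, og)
        assert out.polarized[0]
        assert np.array_equal(out.alleles, ing.alleles)  # ALT stays derived

    def test_outgroup_monomorphic_alt_flips_coding(self):
        ing = ingroup_mat([0, 1, 1, 0])
        og = outgroup_mat([[(1, 1)] * 5])
        out = polarize(ing, og)
        assert out.polarized[0]
        assert out.alleles[:, 0].tolist() == [1, 0, 0, 1]

    def test_too_few_valid_outgroup_genotypes(self):
        ing = ingroup_mat([0, 1, 1, 0])
        og = outgroup_mat([[(0, 0)] * 3 + [(-1, -1)] * 2])
        assert not polarize(ing, og).polarized[0]
        og4 = outgroup_mat([[(0, 0)] * 4 + [(-1, -1)]])
        assert polarize(ing, og4).polarized[0]  # 4 of 5 suffices

    def test_heterozygous_outgroup_is_not_monomorphic(self):
        ing = ingroup_mat([0, 1, 1, 0])
        og = outgroup_mat([[(0, 0)] * 4 + [(0, 1)]])
        assert not polarize(ing, og).polarized[0]

    def test_genotype_multiset_preserved(self, rng):
        hap = random_matrix(rng, 8, 10)
        og_alleles = (rng.random((10, 10)) < 0.2).astype(np.int8)
        og = HaplotypeMatrix(
            og_alleles, hap.positions, "chr1",
            [f"og{i}" for i in range(5)], np.asarray(["OUT"] * 5),
            np.zeros(10, bool),
        )
        out = polarize(hap, og)
        for j in range(10):
            before = sorted(hap.alleles[:, j].tolist())
            after = sorted(out.alleles[:, j].tolist())
            flipped = sorted((1 - hap.alleles[:, j]).tolist())
            assert after in (before, flipped)

    def test_coordinate_mismatch_is_an_error(self, rng):
        hap = random_matrix(rng, 8, 10)
        og = random_matrix(rng, 10, 10, span=20_000)
        with pytest.raises(ValueError, match="coordinates"):
            polarize(hap, og)


# ---------------------------------------------------------------------------
# masks


class TestSiteMask:
    def test_empty_mask_is_identity(self, rng):
        hap = random_matrix(rng, 6, 20)
        mask = SiteMask("chr1", 10_000)
        out = apply_mask(hap, mask)
        assert np.array_equal(out.alleles, hap.alleles)
        assert mask.accessible_bp(0, 10_000) == 10_000

    def test_full_mask_removes_everything(self, rng):
        hap = random_matrix(rng, 6, 20)
        mask = SiteMask.from_intervals("chr1", 10_000, [(0, 10_000)])
        out = apply_mask(hap, mask)
        assert out.n_sites == 0
        assert mask.accessible_bp(0, 10_000) == 0

    def test_accessible_count_arithmetic(self):
        mask = SiteMask.from_intervals("chr1", 50_000, [(12_000, 15_800)])
        assert mask.accessible_bp(10_000, 20_000) == 6_200

    def test_interval_normalization_merges_overlaps(self):
        mask = SiteMask.from_intervals("chr1", 1000, [(10, 50), (40, 80), (80, 90), (200, 210)])
        assert mask.starts.tolist() == [10, 200]
        assert mask.ends.tolist() == [90, 210]

    def test_accessibility_matches_per_base_enumeration(self, rng):
        """Interval arithmetic equals brute-force membership counting."""
        for _ in range(30):
            length = int(rng.integers(1_000, 100_000))
            n_iv = int(rng.integers(0, 20))
            starts = rng.integers(0, length, n_iv)
            lens = rng.integers(1, 2_000, n_iv) if n_iv else np.empty(0, int)
            ivs = [(int(s), int(min(s + l, length))) for s, l in zip(starts, lens)]
            mask = SiteMask.from_intervals("chr1", length, ivs)
            base = np.zeros(length, dtype=bool)
            for s, e in ivs:
                base[s:e] = True
            q0, q1 = sorted(rng.integers(0, length + 1, 2).tolist())
            assert mask.masked_bp(q0, q1) == int(base[q0:q1].sum())
            pos = rng.integers(0, length, 50)
            assert np.array_equal(mask.is_masked(pos), base[pos])

    def test_bed_round_trip(self, tmp_path):
        mask = SiteMask.from_intervals("chr1", 1000, [(10, 40), (100, 200)])
        p = tmp_path / "m.bed"
        mask.to_bed(p)
        back = SiteMask.from_bed(p, "chr1", 1000)
        assert back.starts.tolist() == mask.starts.tolist()
        assert back.ends.tolist() == mask.ends.tolist()

    def test_fasta_hard_mask(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">chr1 desc\nACGTNNNNAC\nGTacgtACGT\n")
        m_n = SiteMask.from_fasta(p, "chr1", dialect="N")
        assert m_n.starts.tolist() == [4] and m_n.ends.tolist() == [8]
        m_b = SiteMask.from_fasta(p, "chr1", dialect="both")
        assert m_b.masked_bp() == 4 + 4

    def test_slice_rebases_coordinates(self):
        mask = SiteMask.from_intervals("chr1", 1000, [(100, 300)])
        sl = mask.slice(150, 500)
        assert sl.starts.tolist() == [0] and sl.ends.tolist() == [150]
        assert sl.length == 500


# ---------------------------------------------------------------------------
# coverage filter


def depth_case(depths):
    depths = np.asarray(depths)
    n_samples, n_sites = depths.shape
    alleles = np.tile(np.array([[0], [1]], dtype=np.int8), (n_samples, n_sites))
    hap = HaplotypeMatrix(
        alleles,
        np.arange(n_sites, dtype=np.int64),
        "chr1",
        [f"s{i}" for i in range(n_samples)],
        np.asarray(["A"] * n_samples),
        np.ones(n_sites, bool),
    )
    return hap, GenotypeDepthMatrix(depths)


class TestCoverageFilter:
    def test_deep_coverage_is_identity(self):
        hap, depth = depth_case(np.full((10, 4), 30))
        out = coverage_filter(hap, depth)
        assert np.array_equal(out.alleles, hap.alleles)

    def test_site_below_80_percent_dropped(self):
        d = np.full((10, 1), 30)
        d[:3, 0] = 2  # 7 of 10 pass: 0.7 < 0.8
        hap, depth = depth_case(d)
        assert coverage_filter(hap, depth).n_sites == 0

    def test_exactly_80_percent_kept_with_missing_genotypes(self):
        d = np.full((10, 1), 30)
        d[:2, 0] = 4  # 8 of 10 pass: boundary holds
        hap, depth = depth_case(d)
        out = coverage_filter(hap, depth)
        assert out.n_sites == 1
        assert (out.alleles[:4, 0] == MISSING).all()
        assert not (out.alleles[4:, 0] == MISSING).any()

    def test_shape_mismatch_is_an_error(self):
        hap, depth = depth_case(np.full((10, 3), 30))
        with pytest.raises(ValueError, match="shape"):
            coverage_filter(hap, GenotypeDepthMatrix(np.full((10, 2), 30)))

    def test_per_population_rule(self):
        d = np.full((10, 1), 30)
        d[:2, 0] = 0  # both failures in population A (5 samples): 3/5 = 0.6
        hap, depth = depth_case(d)
        hap = HaplotypeMatrix(
            hap.alleles, hap.positions, hap.chrom, hap.sample_ids,
            np.asarray(["A"] * 5 + ["B"] * 5), hap.polarized,
        )
        assert coverage_filter(hap, depth, per_population=True).n_sites == 0
        assert coverage_filter(hap, depth, per_population=False).n_sites == 1
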