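"""Nucleotide diversity, Hudson F_ST, sliding windows, outlier calling."""

import itertools

import numpy as np
import pytest

from mamoscan import popgen, simdata
from mamoscan.popgen import (
    HaplotypeMatrix,
    hudson_fst,
    nucleotide_diversity,
    read_haplotype_tsv,
    read_pop_file,
    read_vcf,
    sliding_windows,
    top_quantile_threshold,
)


def brute_force_pi(alleles: np.ndarray, window_length: int) -> float:
    """Oracle: average pairwise difference count over all haplotype pairs,
    with per-site missing-data handling via per-site sample sizes."""
    total = 0.0
    for j in range(alleles.shape[1]):
        col = alleles[:, j]
        col = col[col != -1]
        n = len(col)
        if n < 2:
            continue
        diffs = sum(1 for a, b in itertools.combinations(col, 2) if a != b)
        total += diffs / (n * (n - 1) / 2)
    return total / window_length


def brute_force_fst(alleles, mask_a, mask_b):
    """Oracle: per-site Hw/Hb sums written out longhand."""
    hw_sum, hb_sum, used = 0.0, 0.0, 0
    for j in range(alleles.shape[1]):
        a = alleles[mask_a, j]
        b = alleles[mask_b, j]
        a, b = a[a != -1], b[b != -1]
        na, nb = len(a), len(b)
        if na < 2 or nb < 2:
            continue
        pa, pb = a.mean(), b.mean()
        if (pa == 0 and pb == 0) or (pa == 1 and pb == 1):
            continue
        hw = (2 * pa * (1 - pa) * na / (na - 1)
              + 2 * pb * (1 - pb) * nb / (nb - 1)) / 2
        hb = pa * (1 - pb) + pb * (1 - pa)
        hw_sum += hw
        hb_sum += hb
        used += 1
    if used == 0 or hb_sum == 0:
        return None
    return 1 - (hw_sum / used) / (hb_sum / used)


class TestNucleotideDiversity:
    def test_single_pair_single_difference(self):
        alleles = np.zeros((2, 1), dtype=np.int8)
        alleles[1, 0] = 1
        assert nucleotide_diversity(alleles, 100) == pytest.approx(0.01)

    def test_identical_haplotypes_give_zero(self):
        alleles = np.ones((5, 4), dtype=np.int8)
        assert nucleotide_diversity(alleles, 50) == 0.0

    def test_matches_pairwise_oracle_on_random_windows(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n, s = 10, rng.integers(1, 30)
            alleles = rng.integers(0, 2, (n, s)).astype(np.int8)
            missing = rng.random((n, s)) < 0.1
            alleles[missing] = -1
            got = nucleotide_diversity(alleles, 1000)
            expected = brute_force_pi(alleles, 1000)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        alleles = rng.integers(0, 2, (8, 20)).astype(np.int8)
        shuffled = alleles[rng.permutation(8)]
        assert nucleotide_diversity(alleles, 100) == pytest.approx(
            nucleotide_diversity(shuffled, 100), abs=1e-15
        )

    def test_invalid_length_and_all_missing(self):
        alleles = np.zeros((2, 1), dtype=np.int8)
        with pytest.raises(ValueError):
            nucleotide_diversity(alleles, 0)
        assert nucleotide_diversity(np.full((3, 2), -1, dtype=np.int8), 10) is None


class TestHudsonFst:
    def test_fixed_difference_gives_one(self):
        alleles = np.array([[0], [0], [1], [1]], dtype=np.int8)
        mask_a = np.array([True, True, False, False])
        assert hudson_fst(alleles, mask_a, ~mask_a) == pytest.approx(1.0)

    def test_equal_frequencies_near_zero(self):
        # identical allele frequencies: only the unbiased-correction term
        # remains, a small negative of order 1/(n-1)
        half = np.array([[0]] * 25 + [[1]] * 25, dtype=np.int8)
        alleles = np.vstack([half, half])  # both pops at frequency 0.5
        mask_a = np.arange(100) < 50
        fst = hudson_fst(alleles, mask_a, ~mask_a)
        assert abs(fst) < 0.05

    def test_matches_hand_coded_oracle_on_random_windows(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n, s = 20, rng.integers(1, 10)
            alleles = rng.integers(0, 2, (n, s)).astype(np.int8)
            alleles[rng.random((n, s)) < 0.05] = -1
            mask_a = np.arange(n) < 8
            got = hudson_fst(alleles, mask_a, ~mask_a)
            expected = brute_force_fst(alleles, mask_a, ~mask_a)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetry_in_populations(self):
        rng = np.random.default_rng(5)
        alleles = rng.integers(0, 2, (30, 15)).astype(np.int8)
        mask_a = np.arange(30) < 12
        assert hudson_fst(alleles, mask_a, ~mask_a) == pytest.approx(
            hudson_fst(alleles, ~mask_a, mask_a), abs=1e-15
        )

    def test_monomorphic_window_undefined(self):
        alleles = np.zeros((10, 3), dtype=np.int8)
        mask_a = np.arange(10) < 5
        assert hudson_fst(alleles, mask_a, ~mask_a) is None


class TestSlidingWindows:
    @staticmethod
    def toy_matrix(positions, n_per_pop=4, seed=0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_pop
        alleles = rng.integers(0, 2, (n, len(positions))).astype(np.int8)
        ids = [f"A:{i}" for i in range(n_per_pop)] + [
            f"B:{i}" for i in range(n_per_pop)
        ]
        labels = {s: s.split(":")[0] for s in ids}
        return HaplotypeMatrix(ids, labels, np.array(positions), alleles)

    def test_window_arithmetic(self):
        m = self.toy_matrix(list(range(0, 10_000, 97)))
        stats = sliding_windows(m, region=(0, 10_000), window=5000, step=1000)
        assert [s.start for s in stats] == [0, 1000, 2000, 3000, 4000, 5000]
        assert all(s.end == s.start + 5000 for s in stats)

    def test_empty_window_absent_statistics(self):
        m = self.toy_matrix([100, 200, 9100])
        stats = sliding_windows(m, region=(0, 10_000), window=1000, step=1000)
        gap = [s for s in stats if s.start == 5000][0]
        assert gap.n_sites == 0
        assert gap.pi_A is None and gap.fst is None
        hit = [s for s in stats if s.start == 9000][0]
        assert hit.n_sites == 1 and hit.pi_A is not None

    def test_region_outside_positions_warns_and_returns_empty(self, caplog):
        m = self.toy_matrix([100, 200])
        with caplog.at_level("WARNING"):
            assert sliding_windows(m, region=(50_000, 60_000)) == []
        assert caplog.records

    def test_planted_divergent_window_is_argmax(self):
        matrix, truth = simdata.simulate_haplotypes(seed=123)
        stats = sliding_windows(matrix, window=5000, step=1000)
        best = max((s for s in stats if s.fst is not None), key=lambda s: s.fst)
        lo, hi = truth.planted_fst_window
        assert best.start < hi and best.end > lo


class TestTopQuantile:
    @staticmethod
    def stats_from_values(values):
        return [
            popgen.WindowStat("c", i, i + 1, 1, None, None, float(v))
            for i, v in enumerate(values)
        ]

    def test_linear_interpolation_on_1_to_100(self):
        stats = self.stats_from_values(range(1, 101))
        thr = top_quantile_threshold(stats, "fst", 0.95)
        assert 95.0 < thr < 96.0
        assert thr == pytest.approx(95.05)
        _, flagged = popgen.outlier_windows(stats, "fst", 0.95)
        assert {int(s.fst) for s in flagged} == {96, 97, 98, 99, 100}

    def test_constant_and_single_values(self):
        const = self.stats_from_values([0.3] * 10)
        thr, flagged = popgen.outlier_windows(const, "fst", 0.95)
        assert thr == pytest.approx(0.3)
        assert len(flagged) == 10
        assert top_quantile_threshold(self.stats_from_values([0.7]), "fst",
                                      0.95) == pytest.approx(0.7)

    def test_invalid_quantile(self):
        with pytest.raises(ValueError):
            top_quantile_threshold(self.stats_from_values([1]), "fst", 1.5)


class TestReaders:
    VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=chr9,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr9\t11\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr9\t21\t.\tG\tC\t.\tPASS\t.\tGT\t0/1\t./.\t1/1
chr9\t31\t.\tG\tGA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0
"""

    def test_vcf_reader_splits_diploids_and_skips_indels(self, tmp_path, caplog):
        path = tmp_path / "x.vcf"
        path.write_text(self.VCF_TEXT)
        labels = {"s1": "wild", "s2": "wild", "s3": "domestic"}
        with caplog.at_level("WARNING"):
            m = read_vcf(path, labels)
        assert m.alleles.shape == (6, 2)  # indel site skipped
        assert list(m.positions) == [10, 20]
        assert m.alleles[:, 0].tolist() == [0, 0, 0, 1, 1, 1]
        assert m.alleles[2:4, 1].tolist() == [-1, -1]  # missing genotype
        assert any("non-biallelic" in r.message for r in caplog.records)

    def test_tsv_reader_matches_vcf(self, tmp_path):
        tsv = tmp_path / "h.tsv"
        tsv.write_text(
            "pos\twild:a\twild:b\tdomestic:c\tdomestic:d\n"
            "10\t0\t0\t1\t1\n"
            "20\t0\t1\t.\t1\n"
        )
        m = read_haplotype_tsv(tsv)
        assert m.alleles.shape == (4, 2)
        assert m.alleles[2, 1] == -1
        assert m.pop_labels["wild:a"] == "wild"

    def test_pop_file(self, tmp_path):
        path = tmp_path / "pops.tsv"
        path.write_text("s1\twild\ns2\tdomestic\n")
        assert read_pop_file(path) == {"s1": "wild", "s2": "domestic"}
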