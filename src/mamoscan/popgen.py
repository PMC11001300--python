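"""Sliding-window nucleotide diversity and Hudson's F_ST.

Two-population selection scan over biallelic haplotype data: per-window
nucleotide diversity (pi) within each population, Hudson's F_ST between
them (ratio of averages across sites), and empirical top-quantile
outlier calling.

pi uses the unbiased per-site estimator 2*p*q*n/(n-1) averaged over the
window length; F_ST = 1 - mean(Hw)/mean(Hb) where Hw is the average
unbiased within-population heterozygosity and Hb = pA*qB + pB*qA, with
sites monomorphic across both populations excluded.  Missing calls are
dropped per site with per-site sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class HaplotypeMatrix:
    """Biallelic haplotypes: samples x sites over {0, 1, -1=missing}."""

    sample_ids: list[str]
    pop_labels: dict[str, str]
    positions: np.ndarray  # sorted, 0-based
    alleles: np.ndarray  # int8, shape (n_samples, n_sites)
    seq_id: str = "chr"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.sample_ids), len(self.positions)):
            raise ValueError("alleles must be samples x sites")
        if (np.diff(self.positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")
        if not set(np.unique(self.alleles)).issubset({-1, 0, 1}):
            raise ValueError("alleles must be 0, 1 or -1 (missing)")
        missing = set(self.sample_ids) - set(self.pop_labels)
        if missing:
            raise ValueError(f"samples without a population label: {sorted(missing)}")

    def population_mask(self, pop: str) -> np.ndarray:
        return np.array([self.pop_labels[s] == pop for s in self.sample_ids])

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.pop_labels.values()))


@dataclass
class WindowStat:
    seq_id: str
    start: int
    end: int
    n_sites: int
    pi_A: float | None
    pi_B: float | None
    fst: float | None


def _freqs_and_n(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele frequency and non-missing haplotype count."""
    present = alleles != MISSING
    n = present.sum(axis=0)
    derived = np.where(present, alleles, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, derived / np.maximum(n, 1), np.nan)
    return p, n


def nucleotide_diversity(alleles: np.ndarray, window_length: int) -> float | None:
    """Mean pairwise differences per bp within one population.

    ``alleles`` holds the window's variant sites only (haplotypes x
    sites); invariant positions contribute zero.  Sites with fewer than
    two non-missing haplotypes are excluded.  Returns None when no site
    is usable (pi undefined), 0.0 for a window with usable sites but no
    variation -- and 0.0 for a window containing no variant sites at
    all, which the sliding-window driver distinguishes via n_sites.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if alleles.size == 0:
        return 0.0
    p, n = _freqs_and_n(alleles)
    usable = n >= 2
    if not usable.any():
        return None
    p, n = p[usable], n[usable]
    per_site = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return float(per_site.sum() / window_length)


def hudson_fst(alleles: np.ndarray, mask_a: np.ndarray,
               mask_b: np.ndarray) -> float | None:
    """Hudson's F_ST (ratio of averages) between two populations.

    Sites need >= 2 non-missing haplotypes in each population; sites
    monomorphic across both populations are excluded.  Returns None when
    no between-population heterozygosity remains (F_ST undefined).
    """
    if alleles.size == 0:
        return None
    pa, na = _freqs_and_n(alleles[mask_a])
    pb, nb = _freqs_and_n(alleles[mask_b])
    usable = (na >= 2) & (nb >= 2)
    poly = usable & ~(((pa == 0) & (pb == 0)) | ((pa == 1) & (pb == 1)))
    if not poly.any():
        return None
    pa, na, pb, nb = pa[poly], na[poly], pb[poly], nb[poly]
    hw = (2 * pa * (1 - pa) * na / (na - 1) + 2 * pb * (1 - pb) * nb / (nb - 1)) / 2
    hb = pa * (1 - pb) + pb * (1 - pa)
    mean_hb = hb.mean()
    if mean_hb == 0:
        return None
    return float(1.0 - hw.mean() / mean_hb)


def sliding_windows(matrix: HaplotypeMatrix,
                    region: tuple[int, int] | None = None,
                    window: int = 5000, step: int = 1000,
                    pop_a: str | None = None,
                    pop_b: str | None = None) -> list[WindowStat]:
    """Tile ``region`` with windows and compute pi per population and F_ST.

    Windows with no variant sites carry ``n_sites = 0`` and absent
    statistics.
    """
    if not window >= step >= 1:
        raise ValueError("need window >= step >= 1")
    pops = matrix.populations
    if pop_a is None or pop_b is None:
        if len(pops) != 2:
            raise ValueError("pop_a/pop_b required unless exactly two populations")
        pop_a, pop_b = pops
    mask_a = matrix.population_mask(pop_a)
    mask_b = matrix.population_mask(pop_b)
    if region is None:
        region = (0, int(matrix.positions[-1]) + 1 if len(matrix.positions) else window)
    start, end = region
    if len(matrix.positions) and (
        start > matrix.positions[-1] or end <= matrix.positions[0]
    ):
        logger.warning("region [%d, %d) lies outside the variant positions", start, end)
        return []
    starts = list(range(start, max(start, end - window) + 1, step))
    if not starts:
        starts = [start]
    stats: list[WindowStat] = []
    for ws in starts:
        we = min(ws + window, end)
        lo, hi = np.searchsorted(matrix.positions, [ws, we])
        sites = matrix.alleles[:, lo:hi]
        n_sites = hi - lo
        if n_sites == 0:
            stats.append(WindowStat(matrix.seq_id, ws, we, 0, None, None, None))
            continue
        length = we - ws
        stats.append(
            WindowStat(
                matrix.seq_id, ws, we, int(n_sites),
                nucleotide_diversity(sites[mask_a], length),
                nucleotide_diversity(sites[mask_b], length),
                hudson_fst(sites, mask_a, mask_b),
            )
        )
    return stats


def top_quantile_threshold(stats: Sequence[WindowStat], field: str,
                           q: float = 0.95) -> float:
    """Empirical q-quantile (linear interpolation) of a window statistic."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    values = [getattr(s, field) for s in stats]
    values = [v for v in values if v is not None]
    if not values:
        raise ValueError(f"no defined values for field {field!r}")
    return float(np.quantile(values, q, method="linear"))


def outlier_windows(stats: Sequence[WindowStat], field: str,
                    q: float = 0.95) -> tuple[float, list[WindowStat]]:
    """Threshold plus the windows at or above it."""
    threshold = top_quantile_threshold(stats, field, q)
    flagged = [s for s in stats
               if getattr(s, field) is not None and getattr(s, field) >= threshold]
    return threshold, flagged


# ---------------------------------------------------------------------------
# input readers

def read_pop_file(path) -> dict[str, str]:
    labels = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            labels[sample] = pop
    return labels


def read_vcf(path, pop_labels: dict[str, str]) -> HaplotypeMatrix:
    """Biallelic SNPs from a VCF with GT fields; diploid unphased
    genotypes are split into two haplotype rows per sample.  Multi-allelic
    sites are skipped with a warning; missing genotypes become -1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions: list[int] = []
    columns: list[np.ndarray] = []
    seq_id = "chr"
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            logger.warning("skipping non-biallelic-SNP site at %s:%d",
                           variant.CHROM, variant.POS)
            continue
        seq_id = variant.CHROM
        gts = variant.genotype.array()  # (n_samples, ploidy+1); -1 = missing
        col = gts[:, :2].astype(np.int8).reshape(-1)
        col[col < 0] = MISSING
        positions.append(variant.POS - 1)
        columns.append(col)
    hap_ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    hap_labels = {}
    for s in samples:
        if s not in pop_labels:
            raise ValueError(f"sample {s} has no population label")
        hap_labels[f"{s}_1"] = pop_labels[s]
        hap_labels[f"{s}_2"] = pop_labels[s]
    alleles = (np.column_stack(columns) if columns
               else np.zeros((len(hap_ids), 0), dtype=np.int8))
    return HaplotypeMatrix(hap_ids, hap_labels, np.array(positions, dtype=np.int64),
                           alleles, seq_id=seq_id)


def read_haplotype_tsv(path, pop_labels: dict[str, str] | None = None) -> HaplotypeMatrix:
    """0/1 matrix TSV: header ``pos<TAB>sample...``; '.' = missing.

    When no separate population file is given, sample names are expected
    to look like ``pop:sample``.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        positions, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            positions.append(int(parts[0]))
            rows.append([MISSING if x == "." else int(x) for x in parts[1:]])
    if pop_labels is None:
        pop_labels = {s: s.split(":", 1)[0] for s in samples}
    alleles = (np.array(rows, dtype=np.int8).T if rows
               else np.zeros((len(samples), 0), dtype=np.int8))
    return HaplotypeMatrix(samples, pop_labels, np.array(positions), alleles)


def stats_to_tsv(stats: Sequence[WindowStat], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("seq_id\tstart\tend\tn_sites\tpi_A\tpi_B\tfst\n")
        for s in stats:
            def fmt(v):
                return "" if v is None else f"{v:.6g}"
            fh.write(f"{s.seq_id}\t{s.start}\t{s.end}\t{s.n_sites}\t"
                     f"{fmt(s.pi_A)}\t{fmt(s.pi_B)}\t{fmt(s.fst)}\n")


def outliers_to_bed(stats: Sequence[WindowStat], field: str, q: float, path) -> None:
    threshold, flagged = outlier_windows(stats, field, q)
    with open(path, "w") as fh:
        fh.write(f"# {field} top-quantile threshold (q={q}): {threshold:.6g}\n")
        for s in flagged:
            fh.write(f"{s.seq_id}\t{s.start}\t{s.end}\t{field}\t"
                     f"{getattr(s, field):.6g}\t.\n")
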