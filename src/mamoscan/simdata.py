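"""Synthetic-data generators with exact ground truth for every stage.

These generators stand in for the real study inputs -- a genome
annotation with ~15k genes, a knockout-vs-control DEG table, wild and
domesticated resequencing panels, and qPCR plates -- at desk scale, so
that binding-site recovery, target nomination, the selection scan, and
the fold-change estimator can all be verified against a planted truth.
All generators are pure functions of their parameters plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import false_discovery_control

from .genomeprep import GeneModel, extract_flanks
from .pwmscan import PWM, ALPHABET, consensus, pwm_from_consensus, reverse_complement

# outer margin of a flank kept free of planted sites so clipping at the
# contig edge can never cut a planted site
_EDGE_MARGIN = 10


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    kind: str  # flank kind: upstream | downstream
    offset: int  # within the flank interval, forward genomic coordinates
    strand: str
    site: str  # motif-strand sequence


@dataclass
class TruthTable:
    true_target_genes: set[str] = field(default_factory=set)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    deg_truth: dict[str, float] = field(default_factory=dict)
    planted_fst_window: tuple[int, int] | None = None


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(ALPHABET))[rng.choice(4, size=length, p=probs)])


def _sample_site(rng: np.random.Generator, pwm: PWM, site_strength: float) -> str:
    """Draw a site letter-by-letter from the motif at the given strength.

    The planting distribution keeps the motif's consensus but re-spreads
    each column with ``site_strength`` on the consensus base; strength
    1.0 plants the exact consensus.
    """
    planting = pwm_from_consensus(consensus(pwm), site_strength)
    cols = planting.probs.T
    return "".join(ALPHABET[rng.choice(4, p=col / col.sum())] for col in cols)


def simulate_genome(n_genes: int = 20, contig_length: int = 200_000,
                    flank: int = 2000, pwm: PWM | None = None,
                    n_true_targets: int = 7, site_strength: float = 1.0,
                    gc: float = 0.5, gene_length: int = 1000,
                    seed: int = 0) -> tuple[dict[str, str], str, TruthTable]:
    """Toy genome + GFF3 with binding sites planted in true-target flanks.

    Genes are laid out evenly on one contig with random strands; each of
    ``n_true_targets`` randomly chosen genes receives one site sampled
    from the motif (strength = per-base consensus probability) at a
    uniform offset inside a randomly chosen flank, on a random strand.
    Returns (genome dict, GFF3 text, TruthTable); byte-identical for a
    fixed seed.
    """
    if pwm is None:
        from .fixtures import mamo_s_printed_pwm
        pwm = mamo_s_printed_pwm()
    if not 0 <= n_true_targets <= n_genes:
        raise ValueError("need 0 <= n_true_targets <= n_genes")
    footprint = gene_length + 2 * flank
    if n_genes * footprint > contig_length:
        raise ValueError(
            f"{n_genes} genes x {footprint} bp do not fit in {contig_length} bp"
        )
    rng = np.random.default_rng(seed)
    contig_id = "contig1"
    seq = list(_random_dna(rng, contig_length, gc))
    spacing = contig_length // n_genes
    genes: list[GeneModel] = []
    for i in range(n_genes):
        start = i * spacing + flank
        genes.append(GeneModel(f"g{i + 1:03d}", contig_id, start,
                               start + gene_length, rng.choice(["+", "-"])))
    truth = TruthTable()
    target_idx = sorted(rng.choice(n_genes, size=n_true_targets, replace=False))
    flank_lookup = {
        (f.gene_id, f.kind): f
        for f in extract_flanks({contig_id: "".join(seq)}, genes, flank)
    }
    for i in target_idx:
        gene = genes[i]
        kind = rng.choice(["upstream", "downstream"])
        region = flank_lookup[(gene.gene_id, kind)]
        site = _sample_site(rng, pwm, site_strength)
        w = len(site)
        offset = int(rng.integers(_EDGE_MARGIN, (region.end - region.start) - w
                                  - _EDGE_MARGIN + 1))
        strand = rng.choice(["+", "-"])
        planted = site if strand == "+" else reverse_complement(site)
        pos = region.start + offset
        seq[pos : pos + w] = list(planted)
        truth.true_target_genes.add(gene.gene_id)
        truth.planted_sites.append(PlantedSite(gene.gene_id, kind, offset,
                                               strand, site))
    gff_lines = ["##gff-version 3"]
    for g in genes:
        gff_lines.append(
            f"{g.seq_id}\tsimdata\tgene\t{g.start + 1}\t{g.end}\t.\t"
            f"{g.strand}\t.\tID={g.gene_id}"
        )
    return {contig_id: "".join(seq)}, "\n".join(gff_lines) + "\n", truth


def simulate_deg_table(truth: TruthTable, all_genes: list[str],
                       effect_log2fc: float = 3.0,
                       replicate_noise_sd: float = 0.2, n_reps: int = 3,
                       seed: int = 0, baseline_log2: float = 5.0) -> pd.DataFrame:
    """DEG table in which exactly the true targets carry the planted shift.

    Per gene, ``n_reps`` control and condition replicates are drawn on
    the log2 scale; true-target genes get ``effect_log2fc`` added to the
    condition mean.  Columns: gene_id, log2fc, pvalue, fdr.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 for a t test")
    rng = np.random.default_rng(seed)
    rows = []
    for gene_id in all_genes:
        effect = effect_log2fc if gene_id in truth.true_target_genes else 0.0
        truth.deg_truth[gene_id] = effect
        control = rng.normal(baseline_log2, replicate_noise_sd, n_reps)
        condition = rng.normal(baseline_log2 + effect, replicate_noise_sd, n_reps)
        _, pvalue = stats.ttest_ind(condition, control)
        rows.append((gene_id, condition.mean() - control.mean(), float(pvalue)))
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue"])
    df["fdr"] = false_discovery_control(df["pvalue"], method="bh")
    return df


def simulate_haplotypes(nA: int = 51, nB: int = 171,
                        region_length: int = 50_000,
                        site_density: float = 0.01,
                        diverged_window: tuple[int, int] | None = (20_000, 25_000),
                        divergence_level: float = 0.9,
                        seed: int = 0,
                        pop_a: str = "wild", pop_b: str = "domestic"):
    """Two-population haplotypes with one planted differentiated window.

    Outside the window both populations share each site's allele
    frequency (Uniform(0.05, 0.95)).  Inside it the frequencies are
    separated by exactly ``divergence_level``: pA = u(1-d), pB = pA + d,
    so d = 1 plants fixed differences.  Returns (HaplotypeMatrix,
    TruthTable).
    """
    from .popgen import HaplotypeMatrix

    if not 0 <= divergence_level <= 1:
        raise ValueError("divergence_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    positions = np.nonzero(rng.random(region_length) < site_density)[0]
    n_sites = len(positions)
    u = rng.uniform(0.05, 0.95, size=n_sites)
    pA = u.copy()
    pB = u.copy()
    if diverged_window is not None:
        lo, hi = diverged_window
        if not (0 <= lo < hi <= region_length):
            raise ValueError("diverged_window must lie inside the region")
        inside = (positions >= lo) & (positions < hi)
        pA[inside] = u[inside] * (1 - divergence_level)
        pB[inside] = pA[inside] + divergence_level
    hapA = (rng.random((nA, n_sites)) < pA).astype(np.int8)
    hapB = (rng.random((nB, n_sites)) < pB).astype(np.int8)
    sample_ids = [f"{pop_a}{i + 1}" for i in range(nA)] + [
        f"{pop_b}{i + 1}" for i in range(nB)
    ]
    labels = {s: (pop_a if s.startswith(pop_a) else pop_b) for s in sample_ids}
    matrix = HaplotypeMatrix(sample_ids, labels, positions,
                             np.vstack([hapA, hapB]), seq_id="chr9")
    truth = TruthTable(planted_fst_window=diverged_window)
    return matrix, truth


def simulate_ct_table(genes: list[str] | None = None,
                      groups: tuple[str, str] = ("control", "knockout"),
                      fold_changes: dict[str, float] | float = 4.0,
                      noise_sd: float = 0.1, n_reps: int = 3,
                      seed: int = 0, ref_gene: str = "RpL3",
                      technical_reps: int = 3,
                      baseline_ct: float = 20.0,
                      ref_ct: float = 15.0) -> pd.DataFrame:
    """Long-format Ct table with known fold changes.

    The reference gene has a constant expected Ct in every sample; each
    target gene's Ct in the non-calibrator group is shifted by
    -log2(fold change).  Gaussian noise of ``noise_sd`` cycles is added
    to every measurement.  Columns: sample, group, gene, replicate, ct.
    """
    if genes is None:
        genes = ["yellow"]
    if not isinstance(fold_changes, dict):
        fold_changes = {g: float(fold_changes) for g in genes}
    if any(f <= 0 for f in fold_changes.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    calibrator, treated = groups
    rows = []
    for group in groups:
        for b in range(1, n_reps + 1):
            sample = f"{group}_s{b}"
            for gene in list(genes) + [ref_gene]:
                if gene == ref_gene:
                    expected = ref_ct
                elif group == calibrator:
                    expected = baseline_ct
                else:
                    expected = baseline_ct - np.log2(fold_changes[gene])
                for t in range(1, technical_reps + 1):
                    ct = expected + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append((sample, group, gene, t, ct))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])


def truth_to_tsv(truth: TruthTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# true_target_genes: " + ",".join(sorted(truth.true_target_genes))
                 + "\n")
        if truth.planted_fst_window is not None:
            lo, hi = truth.planted_fst_window
            fh.write(f"# planted_fst_window: {lo}-{hi}\n")
        fh.write("gene_id\tflank_kind\toffset\tstrand\tsite\n")
        for s in truth.planted_sites:
            fh.write(f"{s.gene_id}\t{s.kind}\t{s.offset}\t{s.strand}\t{s.site}\n")
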