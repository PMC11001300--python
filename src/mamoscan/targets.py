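"""Candidate direct-target nomination: flank motif hits x DEG table.

A gene is nominated as a candidate direct target when it has at least
one binding-site hit in its 2-kb flanks AND it is a significant DEG
(|log2FC| and FDR thresholds both configurable).  Genes absent from the
DEG table are carried along un-nominated.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pwmscan import MotifHit

DEFAULT_FC_THRESHOLD = 1.0
DEFAULT_FDR_THRESHOLD = 0.05


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2fc: float
    pvalue: float
    fdr: float

    def is_significant(self, fc_threshold: float = DEFAULT_FC_THRESHOLD,
                       fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> bool:
        return abs(self.log2fc) >= fc_threshold and self.fdr <= fdr_threshold


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    n_hits_up: int
    n_hits_down: int
    best_pvalue: float | None
    deg: DEGRecord | None
    nominated: bool


def gene_of_flank(seq_id: str) -> tuple[str, str]:
    """Split a ``gene|up`` / ``gene|down`` flank FASTA id."""
    gene_id, _, suffix = seq_id.rpartition("|")
    if suffix not in ("up", "down") or not gene_id:
        raise ValueError(f"{seq_id!r} is not a geneID|up / geneID|down flank id")
    kind = "upstream" if suffix == "up" else "downstream"
    return gene_id, kind


def annotate_hits(hits: Iterable[MotifHit]) -> list[tuple[str, str, MotifHit]]:
    """(gene_id, flank kind, hit) triples from flank-scan hits."""
    return [(*gene_of_flank(h.seq_id), h) for h in hits]


def count_genes_with_hits(annotated_hits: Sequence[tuple[str, str, MotifHit]]) -> int:
    """Number of distinct genes carrying at least one hit."""
    return len({gene_id for gene_id, _, _ in annotated_hits})


def read_deg_table(path) -> list[DEGRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["gene_id", "log2fc", "pvalue", "fdr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"DEG table is missing columns: {missing}")
    return [
        DEGRecord(str(r.gene_id), float(r.log2fc), float(r.pvalue), float(r.fdr))
        for r in df.itertuples()
    ]


def nominate(annotated_hits: Sequence[tuple[str, str, MotifHit]],
             degs: Sequence[DEGRecord],
             fc_threshold: float = DEFAULT_FC_THRESHOLD,
             fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
             all_genes: Iterable[str] | None = None) -> list[TargetCall]:
    """One TargetCall per gene in the union of hits, DEGs and ``all_genes``.

    nominated <=> (>= 1 flank hit) AND the gene is a significant DEG.
    Output is sorted by best hit p-value then gene id; genes without
    hits sort last.  Duplicate gene ids in the DEG table are an error.
    """
    dup = [g for g, n in Counter(d.gene_id for d in degs).items() if n > 1]
    if dup:
        raise ValueError(f"duplicate gene_id rows in DEG table: {sorted(dup)}")
    deg_by_gene = {d.gene_id: d for d in degs}

    up_counts: dict[str, int] = defaultdict(int)
    down_counts: dict[str, int] = defaultdict(int)
    best_p: dict[str, float] = {}
    for gene_id, kind, hit in annotated_hits:
        if kind == "upstream":
            up_counts[gene_id] += 1
        else:
            down_counts[gene_id] += 1
        if gene_id not in best_p or hit.pvalue < best_p[gene_id]:
            best_p[gene_id] = hit.pvalue

    genes = set(best_p) | set(deg_by_gene)
    if all_genes is not None:
        genes |= set(all_genes)
    calls = []
    for gene_id in genes:
        deg = deg_by_gene.get(gene_id)
        n_up, n_down = up_counts.get(gene_id, 0), down_counts.get(gene_id, 0)
        nominated = (
            (n_up + n_down) >= 1
            and deg is not None
            and deg.is_significant(fc_threshold, fdr_threshold)
        )
        calls.append(TargetCall(gene_id, n_up, n_down, best_p.get(gene_id),
                                deg, nominated))
    calls.sort(key=lambda c: (c.best_pvalue is None,
                              c.best_pvalue if c.best_pvalue is not None else 0.0,
                              c.gene_id))
    return calls


def summarize(calls: Sequence[TargetCall],
              fc_threshold: float = DEFAULT_FC_THRESHOLD,
              fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> dict[str, int]:
    return {
        "total_genes": len(calls),
        "genes_with_hits": sum(1 for c in calls if c.n_hits_up + c.n_hits_down),
        "significant_degs": sum(
            1 for c in calls
            if c.deg is not None and c.deg.is_significant(fc_threshold, fdr_threshold)
        ),
        "nominated": sum(1 for c in calls if c.nominated),
    }


def calls_to_tsv(calls: Sequence[TargetCall], path,
                 header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("gene_id\tn_hits_up\tn_hits_down\tbest_pvalue\t"
                 "log2fc\tfdr\tnominated\n")
        for c in calls:
            bp = "" if c.best_pvalue is None else f"{c.best_pvalue:.6g}"
            fc = "" if c.deg is None else f"{c.deg.log2fc:.4f}"
            fdr = "" if c.deg is None else f"{c.deg.fdr:.6g}"
            fh.write(f"{c.gene_id}\t{c.n_hits_up}\t{c.n_hits_down}\t{bp}\t"
                     f"{fc}\t{fdr}\t{int(c.nominated)}\n")
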