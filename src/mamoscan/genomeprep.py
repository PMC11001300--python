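"""Gene-model parsing, strand-aware flank extraction, and ORF calling.

Flanks are taken relative to the annotated gene span (not per-transcript
TSS): for a + strand gene the upstream flank is the ``flank`` bp ending
at the gene start; for a - strand gene the mirror image, with the
sequence reverse-complemented so every flank reads 5'->3' relative to
its gene.  Flanks are clipped (and flagged truncated) at contig edges
and are deliberately not trimmed when they overlap a neighboring gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    seq_id: str
    start: int  # 0-based half-open
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.gene_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class FlankRegion:
    gene_id: str
    kind: str  # "upstream" | "downstream"
    seq_id: str
    start: int  # 0-based half-open, forward-strand genomic coordinates
    end: int
    sequence: str  # 5'->3' relative to the gene
    truncated: bool

    @property
    def name(self) -> str:
        suffix = "up" if self.kind == "upstream" else "down"
        return f"{self.gene_id}|{suffix}"


@dataclass(frozen=True)
class OrfCall:
    transcript_id: str
    start: int  # 0-based half-open on the given strand
    end: int
    length: int  # nucleotides, including the stop codon


def _parse_gff_attributes(col: str) -> dict[str, str]:
    out = {}
    for item in col.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gff(gff_text: str, feature_type: str = "gene") -> list[GeneModel]:
    """GFF3 ``gene`` records as 0-based half-open GeneModels, sorted.

    Malformed records (end < start, unknown strand, too few columns) are
    skipped with a warning naming the line number.
    """
    genes: list[GeneModel] = []
    seen = 0
    for lineno, line in enumerate(gff_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 9:
            logger.warning("GFF line %d: fewer than 9 columns, skipped", lineno)
            continue
        if cols[2] != feature_type:
            continue
        seen += 1
        try:
            start1, end1 = int(cols[3]), int(cols[4])
        except ValueError:
            logger.warning("GFF line %d: non-integer coordinates, skipped", lineno)
            continue
        if end1 < start1:
            logger.warning("GFF line %d: end < start, skipped", lineno)
            continue
        if cols[6] not in "+-":
            logger.warning("GFF line %d: unknown strand %r, skipped", lineno, cols[6])
            continue
        attrs = _parse_gff_attributes(cols[8])
        gene_id = attrs.get("ID") or attrs.get("gene_id") or f"gene_line{lineno}"
        genes.append(GeneModel(gene_id, cols[0], start1 - 1, end1, cols[6]))
    genes.sort(key=lambda g: (g.seq_id, g.start))
    return genes


def read_gff(path, feature_type: str = "gene") -> list[GeneModel]:
    with open(path) as fh:
        return parse_gff(fh.read(), feature_type)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def extract_flanks(genome: Mapping[str, str], genes: list[GeneModel],
                   flank: int = 2000) -> list[FlankRegion]:
    """Upstream/downstream flanks of every gene, clipped at contig edges."""
    if flank < 1:
        raise ValueError("flank size must be >= 1")
    out: list[FlankRegion] = []
    for gene in genes:
        contig = genome.get(gene.seq_id)
        if contig is None:
            raise KeyError(
                f"gene {gene.gene_id}: contig {gene.seq_id!r} not in genome"
            )
        clen = len(contig)
        left = (max(0, gene.start - flank), gene.start)
        right = (gene.end, min(clen, gene.end + flank))
        if gene.strand == "+":
            intervals = [("upstream", left), ("downstream", right)]
        else:
            intervals = [("upstream", right), ("downstream", left)]
        for kind, (s, e) in intervals:
            seq = contig[s:e]
            if gene.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            wanted = flank
            truncated = (e - s) < wanted
            out.append(FlankRegion(gene.gene_id, kind, gene.seq_id, s, e,
                                   seq, truncated))
    return out


def flanks_to_fasta(flanks: list[FlankRegion], path) -> None:
    with open(path, "w") as fh:
        for f in flanks:
            fh.write(f">{f.name}\n{f.sequence}\n")


def flanks_to_bed(flanks: list[FlankRegion], path) -> None:
    with open(path, "w") as fh:
        for f in flanks:
            fh.write(f"{f.seq_id}\t{f.start}\t{f.end}\t{f.name}\t0\t.\n")


def longest_orf(transcript: str, transcript_id: str = "transcript") -> OrfCall | None:
    """Longest ATG-initiated, stop-terminated ORF in the three forward frames.

    Length includes the stop codon; ties are broken by the smallest
    start.  Returns None when no complete ORF exists.
    """
    seq = transcript.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("transcript must be over A/C/G/T/N")
    best: OrfCall | None = None
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                length = i + 3 - start
                if best is None or length > best.length or (
                    length == best.length and start < best.start
                ):
                    best = OrfCall(transcript_id, start, i + 3, length)
                start = None
        # an unterminated ATG...end run is not a complete ORF
    return best
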