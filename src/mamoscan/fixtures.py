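"""Packaged reference objects: the printed-consensus motif and synthetic
stand-in transcripts.

``mamo_s_printed_pwm`` is the Bm-mamo-S binding-site model anchored on
the printed 9-bp consensus GTGCGTGGC (per-base match probability 0.97),
shipped so the downstream stages have a motif that does not depend on
the recognition-code table.  The numeric column values of the original
server-predicted PWM are not public; only the consensus is.

``synthetic_mamo_transcripts`` builds deterministic SYNTHETIC mRNA
stand-ins whose longest open reading frames have, by construction, the
lengths reported for the two real transcripts (2397 bp for the long
form, 1824 bp for the short form).  They share no sequence with the
deposited records and exist so the ORF caller can be exercised offline;
use ``fetch_genbank_fasta`` to run the same check on the real records
when network access is available.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .pwmscan import PWM, read_meme

MAMO_S_CONSENSUS = "GTGCGTGGC"
# EMSA-validated core shared with the fly ortholog's binding site
MAMO_CORE = "TGCGT"
# site upstream of the silkworm yellow gene bound in vitro
YELLOW_UPSTREAM_SITE = "CTGCGTGGT"

MAMO_L_ORF_LENGTH = 2397
MAMO_S_ORF_LENGTH = 1824


def mamo_s_printed_pwm() -> PWM:
    """The packaged Bm-mamo-S consensus motif (width 9, match prob 0.97)."""
    ref = resources.files("mamoscan").joinpath("data/bm_mamo_s_printed.meme")
    with resources.as_file(ref) as path:
        return read_meme(path)[0]


def _codons_without_stops(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame coding sequence free of stop codons."""
    bases = "ACGT"
    out = []
    while len(out) < n_codons:
        codon = "".join(bases[b] for b in rng.integers(0, 4, 3))
        if codon not in ("TAA", "TAG", "TGA"):
            out.append(codon)
    return "".join(out)


def _synthetic_transcript(orf_length: int, utr5: int, utr3: int,
                          seed: int) -> str:
    """SYNTHETIC transcript with a unique longest ORF of ``orf_length`` nt.

    Layout: stop-free 5' UTR framing, ATG + (orf_length/3 - 2) non-stop
    codons + TAA, then a 3' UTR.  UTRs are seeded with in-frame stops so
    no spurious longer ORF can arise in any frame.
    """
    if orf_length % 3:
        raise ValueError("orf_length must be a multiple of 3")
    rng = np.random.default_rng(seed)
    # UTRs made of TAA repeats interleaved with random bases kill long
    # spurious ORFs in every frame while staying deterministic
    utr5_seq = ("TAA" * (utr5 // 3 + 1))[:utr5]
    utr3_seq = ("TGA" * (utr3 // 3 + 1))[:utr3]
    body = "ATG" + _codons_without_stops(rng, orf_length // 3 - 2) + "TAA"
    return utr5_seq + body + utr3_seq


def synthetic_mamo_transcripts() -> dict[str, str]:
    """Deterministic synthetic stand-ins for the two mamo transcripts.

    Keys name the stand-ins explicitly as synthetic; longest-ORF lengths
    are 2397 and 1824 nt by construction.
    """
    return {
        "synthetic_mamo_L": _synthetic_transcript(MAMO_L_ORF_LENGTH, 120, 300, 11),
        "synthetic_mamo_S": _synthetic_transcript(MAMO_S_ORF_LENGTH, 120, 200, 12),
    }


def fetch_genbank_fasta(accessions: list[str], email: str = "user@example.org",
                        timeout: float = 30.0) -> dict[str, str]:
    """Download nucleotide records from GenBank (network required).

    Returns accession -> sequence.  Intended for the optional check of
    the ORF caller against the deposited mamo transcripts (PP426589,
    PP426590); everything else in the package runs offline.
    """
    from io import StringIO
    from urllib.request import urlopen

    from Bio import SeqIO

    url = (
        "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
        f"?db=nuccore&id={','.join(accessions)}&rettype=fasta&retmode=text"
        f"&email={email}"
    )
    with urlopen(url, timeout=timeout) as fh:
        text = fh.read().decode()
    return {rec.id.split(".")[0]: str(rec.seq)
            for rec in SeqIO.parse(StringIO(text), "fasta")}
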