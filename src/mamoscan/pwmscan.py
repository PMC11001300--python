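"""Position-weight-matrix scanning with exact p-values.

Implements the scoring core of a FIMO-style motif scanner: log-odds
scoring of a PWM against a 0-order background, exact p-values for the
null score distribution computed by dynamic programming over
discretized per-column scores, both-strand scanning, and
Benjamini-Hochberg q-values for the resulting hit list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import false_discovery_control

ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BG = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3 and N as 4; reject anything else."""
    table = np.full(256, -1, dtype=np.int8)
    for c, i in _IDX.items():
        table[ord(c)] = i
        table[ord(c.lower())] = i
    table[ord("N")] = 4
    table[ord("n")] = 4
    arr = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(arr < 0)[0][:5]})
        raise ValueError(f"non-DNA letters in sequence: {bad}")
    return arr


@dataclass
class PWM:
    """Probability matrix over {A, C, G, T}, rows in alphabetical order.

    ``probs`` has shape (4, width).  ``background`` is the 0-order model
    the log-odds scores are taken against; ``pseudocount`` is mixed into
    the probabilities (rescaled) before taking logs so that zero cells
    never produce -inf.
    """

    id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise ValueError("probs must be a 4 x width matrix")
        if (self.probs < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def smoothed(self) -> np.ndarray:
        """Pseudocount-regularized probabilities (columns re-normalized)."""
        if self.pseudocount == 0:
            return self.probs
        p = self.probs + self.pseudocount * self.background[:, None]
        return p / (1.0 + self.pseudocount)

    def log_odds(self) -> np.ndarray:
        """log2(p / background) per cell; raises if a log(0) would arise."""
        p = self.smoothed()
        if (p == 0).any() or (self.background == 0).any():
            raise ValueError(
                "zero probability cell with pseudocount 0; set pseudocount > 0"
            )
        return np.log2(p / self.background[:, None])

    def with_background(self, background: np.ndarray) -> "PWM":
        return PWM(self.id, self.probs.copy(), np.asarray(background, float),
                   self.pseudocount)

    def reverse_complement(self) -> "PWM":
        return PWM(self.id + "_rc", self.probs[::-1, ::-1].copy(),
                   self.background.copy(), self.pseudocount)


def pwm_from_consensus(consensus: str, match_prob: float = 0.97,
                       id: str | None = None, **kw) -> PWM:
    """Build a PWM that puts ``match_prob`` on each consensus base.

    The remaining mass is split evenly over the other three letters.
    """
    consensus = consensus.upper()
    if not consensus or any(c not in _IDX for c in consensus):
        raise ValueError("consensus must be a non-empty string over A/C/G/T")
    if not 0.25 < match_prob <= 1.0:
        raise ValueError("match_prob must be in (0.25, 1]")
    w = len(consensus)
    probs = np.full((4, w), (1.0 - match_prob) / 3.0)
    for j, c in enumerate(consensus):
        probs[_IDX[c], j] = match_prob
    return PWM(id or f"consensus_{consensus}", probs, **kw)


def consensus(pwm: PWM) -> str:
    """Per-column argmax letter; ties go to the alphabetically first base."""
    return "".join(ALPHABET[i] for i in np.argmax(pwm.probs, axis=0))


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int
    strand: str
    score: float
    pvalue: float
    matched_seq: str
    qvalue: float | None = None

    @property
    def stop(self) -> int:
        return self.start + len(self.matched_seq)


_EXACT_WIDTH_LIMIT = 10  # 4^10 words is still cheap to enumerate
_SCORE_TOL = 1e-9  # absorbs summation-order float noise at the boundary


class ScoreDistribution:
    """Null distribution of PWM log-odds scores under the background.

    For widths up to 10 the distribution is built by full enumeration of
    all 4^W words (exact); for wider motifs per-column scores are
    discretized onto a shared integer grid (``granularity`` bins over
    the widest column range) and the total-score pmf is built by DP
    convolution.  The survival function is right-continuous,
    non-increasing, and equals 1 at the minimum score.
    """

    def __init__(self, pwm: PWM, granularity: int = 1000, method: str = "auto"):
        if granularity < 100:
            raise ValueError("granularity must be >= 100")
        if method not in ("auto", "exact", "dp"):
            raise ValueError("method must be 'auto', 'exact' or 'dp'")
        lom = pwm.log_odds()
        self.log_odds = lom
        self.width = pwm.width
        if method == "auto":
            self.exact = pwm.width <= _EXACT_WIDTH_LIMIT
        else:
            self.exact = method == "exact"
            if self.exact and pwm.width > _EXACT_WIDTH_LIMIT:
                raise ValueError(
                    f"exact enumeration is limited to width {_EXACT_WIDTH_LIMIT}"
                )
        bg = pwm.background
        if self.exact:
            # left-to-right accumulation over columns, matching the order
            # used when scoring a single window
            scores = np.zeros(1)
            probs = np.ones(1)
            for j in range(pwm.width):
                scores = (scores[:, None] + lom[:, j][None, :]).ravel()
                probs = (probs[:, None] * bg[None, :]).ravel()
            order = np.argsort(-scores, kind="stable")
            self._levels_desc = scores[order]
            self._cum = np.cumsum(probs[order])
            self.max_score = float(self._levels_desc[0])
            return
        col_min = lom.min(axis=0)
        col_range = (lom.max(axis=0) - col_min).max()
        self.scale = granularity / col_range if col_range > 0 else 1.0
        self.offset = col_min.sum()
        # integer score lookup table, shape (4, width), all entries >= 0
        self.lut = np.rint((lom - col_min[None, :]) * self.scale).astype(np.int64)
        max_total = int(self.lut.max(axis=0).sum())
        pmf = np.zeros(max_total + 1)
        pmf[0] = 1.0
        for j in range(pwm.width):
            new = np.zeros_like(pmf)
            for a in range(4):
                q = self.lut[a, j]
                if bg[a] > 0:
                    new[q:] += bg[a] * pmf[: len(pmf) - q if q else None]
            pmf = new
        # survival[k] = P(integer score >= k)
        self.survival = np.concatenate([pmf[::-1].cumsum()[::-1], [0.0]])
        self.max_int = max_total

    def int_score(self, encoded_window: np.ndarray) -> int:
        if self.exact:
            raise AttributeError("integer scores exist only in DP mode")
        return int(self.lut[encoded_window, np.arange(len(encoded_window))].sum())

    def pvalue_int(self, k: int) -> float:
        if k <= 0:
            return 1.0
        if k > self.max_int:
            return 0.0
        return float(self.survival[k])

    def pvalues_for_scores(self, scores: np.ndarray) -> np.ndarray:
        """Vectorized P(null >= s) for float log-odds scores (exact mode)."""
        idx = np.searchsorted(-self._levels_desc,
                              -(np.asarray(scores, float) - _SCORE_TOL),
                              side="right")
        out = np.zeros(len(scores))
        nonzero = idx > 0
        out[nonzero] = self._cum[idx[nonzero] - 1]
        return out

    def word_pvalue(self, encoded_word: np.ndarray) -> float:
        """P-value of one width-W word, mode-agnostic."""
        if self.exact:
            s = 0.0
            for j, a in enumerate(encoded_word):
                s += self.log_odds[a, j]
            return float(self.pvalues_for_scores(np.array([s]))[0])
        return self.pvalue_int(self.int_score(encoded_word))

    def pvalue(self, score: float) -> float:
        """P(null score >= ``score``) for a float log-odds score (bits)."""
        if score == -math.inf:
            return 1.0
        if self.exact:
            return float(self.pvalues_for_scores(np.array([score]))[0])
        k = int(math.ceil((score - self.offset) * self.scale - 1e-9))
        return self.pvalue_int(k)


def exact_pvalues(pwm: PWM, granularity: int = 1000,
                  method: str = "auto") -> ScoreDistribution:
    """Exact score -> p-value map for ``pwm`` under its background model.

    ``method``: "exact" enumerates all 4^W words (width <= 10), "dp" uses
    discretized dynamic programming, "auto" picks by width.
    """
    return ScoreDistribution(pwm, granularity, method)


def estimate_background(sequences: Iterable[str],
                        symmetrize: bool = True) -> np.ndarray:
    """0-order background from sequence composition (uniform fallback).

    With ``symmetrize`` the complement strands are pooled so that one
    null distribution serves both scanned strands.
    """
    counts = np.zeros(4)
    for seq in sequences:
        arr = _encode(seq)
        counts += np.bincount(arr[arr < 4], minlength=4)
    if counts.sum() == 0:
        return UNIFORM_BG.copy()
    if symmetrize:
        counts = counts + counts[::-1]
    return counts / counts.sum()


def _window_scores(arr: np.ndarray, lut: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Window scores under a per-column lookup table, plus a no-N mask.

    Accumulates column by column (left to right), so float scores match
    a per-word left-to-right summation bit for bit.
    """
    w = lut.shape[1]
    n_win = len(arr) - w + 1
    safe = np.where(arr == 4, 0, arr)
    total = np.zeros(n_win, dtype=lut.dtype)
    has_n = np.zeros(n_win, dtype=bool)
    for j in range(w):
        col = safe[j : j + n_win]
        total += lut[col, j]
        has_n |= arr[j : j + n_win] == 4
    return total, ~has_n


def scan(sequence: str, pwm: PWM, p_threshold: float = 1e-4,
         both_strands: bool = True, seq_id: str = "seq",
         background: np.ndarray | None = None,
         granularity: int = 1000,
         dist: ScoreDistribution | None = None) -> list[MotifHit]:
    """All windows whose match p-value is <= ``p_threshold``.

    Windows containing N are skipped.  Minus-strand hits are reported on
    forward-strand coordinates (start = leftmost base) with
    ``matched_seq`` given on the motif-matching strand.  When no explicit
    background is supplied (and no prebuilt ``dist``), a strand-symmetric
    0-order model is estimated from the scanned sequence itself.
    """
    arr = _encode(sequence)
    w = pwm.width
    if w > len(arr):
        return []
    if dist is None:
        if background is None:
            background = estimate_background([sequence])
        pwm = pwm.with_background(background)
        dist = exact_pvalues(pwm, granularity)
    hits: list[MotifHit] = []
    base_lut = dist.log_odds if dist.exact else dist.lut
    strands = [("+", base_lut)]
    if both_strands:
        # scoring the forward window with the complemented/reversed LUT
        # equals scoring its reverse complement with the motif itself, so
        # one null distribution serves both strands
        strands.append(("-", base_lut[::-1, ::-1]))
    for strand, lut in strands:
        totals, valid = _window_scores(arr, lut)
        if dist.exact:
            pvals = dist.pvalues_for_scores(totals)
        else:
            pvals = np.array([dist.pvalue_int(int(t)) for t in totals])
        keep = valid & (pvals <= p_threshold)
        for i in np.nonzero(keep)[0]:
            window = sequence[i : i + w].upper()
            matched = window if strand == "+" else reverse_complement(window)
            if dist.exact:
                score = float(totals[i])
            else:
                score = float(dist.log_odds[_encode(matched), np.arange(w)].sum())
            hits.append(MotifHit(seq_id, int(i), strand, score,
                                 float(pvals[i]), matched))
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def scan_many(sequences: dict[str, str], pwm: PWM, p_threshold: float = 1e-4,
              both_strands: bool = True, background: np.ndarray | None = None,
              granularity: int = 1000) -> list[MotifHit]:
    """Scan a set of sequences with one shared background/null model."""
    if background is None:
        background = estimate_background(sequences.values())
    pwm = pwm.with_background(background)
    dist = exact_pvalues(pwm, granularity)
    hits: list[MotifHit] = []
    for seq_id in sorted(sequences):
        hits.extend(
            scan(sequences[seq_id], pwm, p_threshold, both_strands,
                 seq_id=seq_id, granularity=granularity, dist=dist)
        )
    return hits


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values."""
    if len(pvalues) == 0:
        return []
    p = np.asarray(pvalues, dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return false_discovery_control(p, method="bh").tolist()


def assign_qvalues(hits: Sequence[MotifHit]) -> list[MotifHit]:
    qs = bh_fdr([h.pvalue for h in hits])
    return [
        MotifHit(h.seq_id, h.start, h.strand, h.score, h.pvalue, h.matched_seq, q)
        for h, q in zip(hits, qs)
    ]


# ---------------------------------------------------------------------------
# I/O: MEME minimal motif format, TSV, BED

def write_meme(pwms: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else UNIFORM_BG
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} {bg[i]:.6f}" for i, c in enumerate(ALPHABET)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for col in pwm.probs.T:
                fh.write(" " + " ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    pwms: list[PWM] = []
    background = UNIFORM_BG.copy()
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array(
                [float(parts[parts.index(c) + 1]) for c in ALPHABET]
            )
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            header = lines[i]
            w = int(header.split("w=")[1].split()[0])
            cols = []
            for j in range(w):
                cols.append([float(x) for x in lines[i + 1 + j].split()])
            pwms.append(PWM(motif_id, np.array(cols).T, background))
            i += 1 + w
            continue
        i += 1
    return pwms


def pwm_to_tsv(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tA\tC\tG\tT\n")
        for j, col in enumerate(pwm.probs.T):
            fh.write(f"{j}\t" + "\t".join(f"{x:.6f}" for x in col) + "\n")


def hits_to_tsv(hits: Sequence[MotifHit], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("seq_id\tstart\tstop\tstrand\tscore\tpvalue\tqvalue\tmatched_seq\n")
        for h in hits:
            q = "" if h.qvalue is None else f"{h.qvalue:.6g}"
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.stop}\t{h.strand}\t"
                f"{h.score:.4f}\t{h.pvalue:.6g}\t{q}\t{h.matched_seq}\n"
            )


def hits_to_bed(hits: Sequence[MotifHit], path) -> None:
    """6-column BED; the score column maps -log10(p) onto 0-1000."""
    with open(path, "w") as fh:
        for h in hits:
            bed_score = int(min(1000, round(-100 * math.log10(max(h.pvalue, 1e-300)))))
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.stop}\t{h.seq_id}:{h.start}\t"
                f"{bed_score}\t{h.strand}\n"
            )
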