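"""C2H2 zinc-finger detection and DNA-binding-site prediction.

A C2H2 finger is detected from the classical Cys2His2 spacing pattern
C-x(1,4)-C-x(12)-H-x(3,5)-H.  Within each finger the DNA-contacting
residues of the recognition helix are read off by the standard
numbering: helix position 1 is the first residue of the alpha-helix
(six residues before the first coordinating histidine), position -1 is
the residue immediately N-terminal to it, and positions -1, 2, 3 and 6
carry the base-specificity information.

Under the canonical binding model each finger reads a 3-bp subsite with
the fingers arrayed antiparallel to the DNA: the C-terminal finger's
triplet sits at the 5' end of the motif, and within a finger residue 6
contacts base 1, residue 3 base 2, and residue -1 base 3 of the
sense-strand triplet.  Residue 2 contacts the complementary strand of
the base 3'-adjacent to the triplet and can optionally contribute a
fourth column.  Residue-to-base preferences come from a plain-text
recognition-code table that the user can replace.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .pwmscan import PWM, UNIFORM_BG

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
HELIX_LABELS = (-1, 1, 2, 3, 4, 5, 6)

# C-x(1,4)-C-x(12)-H-x(3,5)-H with capture groups for the spacers
_ZF_RE = re.compile(r"C(.{1,4})C(.{12})H(.{3,5})H")

# complementary-strand preference: swap A<->T and C<->G
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])


@dataclass
class ZincFinger:
    index: int
    span: tuple[int, int]
    sequence: str
    helix_residues: dict[int, str]
    confidence: float

    def __post_init__(self) -> None:
        if set(self.helix_residues) != set(HELIX_LABELS):
            raise ValueError("helix_residues must cover labels -1 and 1..6")
        if self.span[1] - self.span[0] != len(self.sequence):
            raise ValueError("span length must equal sequence length")


@dataclass
class ZincFingerArray:
    protein_id: str
    fingers: list[ZincFinger]

    def __post_init__(self) -> None:
        spans = [f.span for f in self.fingers]
        if spans != sorted(spans):
            raise ValueError("fingers must be sorted N->C")
        for a, b in zip(spans, spans[1:]):
            if b[0] < a[1]:
                raise ValueError("finger spans must not overlap")


class RecognitionCodeTable:
    """Map (helix position label, residue) -> base probability vector.

    A coarse, qualitative residue->base preference table; residues
    without an entry fall back to ``default_vector`` (uniform unless
    configured otherwise), with a warning logged.
    """

    def __init__(self, entries: dict[tuple[int, str], np.ndarray],
                 default_vector: np.ndarray | None = None):
        self.entries = {}
        for key, vec in entries.items():
            vec = np.asarray(vec, dtype=float)
            if (vec < 0).any() or not np.isclose(vec.sum(), 1.0, atol=1e-9):
                raise ValueError(f"probability vector for {key} must sum to 1")
            self.entries[key] = vec
        self.default_vector = (
            UNIFORM_BG.copy() if default_vector is None
            else np.asarray(default_vector, dtype=float)
        )
        if not np.isclose(self.default_vector.sum(), 1.0, atol=1e-9):
            raise ValueError("default_vector must sum to 1")

    def lookup(self, label: int, residue: str) -> np.ndarray:
        vec = self.entries.get((label, residue))
        if vec is None:
            logger.warning(
                "no recognition-code entry for position %s residue %s; "
                "using the uniform fallback", label, residue,
            )
            return self.default_vector.copy()
        return vec.copy()

    @classmethod
    def from_tsv(cls, path) -> "RecognitionCodeTable":
        entries: dict[tuple[int, str], np.ndarray] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["position_label", "residue", "pA", "pC", "pG", "pT"]
            if header != expected:
                raise ValueError(f"recognition code TSV must have columns {expected}")
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                label, res, *ps = line.rstrip("\n").split("\t")
                entries[(int(label), res)] = np.array([float(x) for x in ps])
        return cls(entries)

    @classmethod
    def default(cls) -> "RecognitionCodeTable":
        ref = resources.files("mamoscan").joinpath("data/recognition_code.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def _confidence(protein: str, start: int, g1: str, g2: str) -> float:
    """Heuristic plausibility score for a pattern match.

    1.0 for the bare C2H2 pattern, plus 0.5 when helix position 4 is
    hydrophobic and 0.5 when an aromatic residue sits within the three
    positions N-terminal of the first cysteine -- two hallmarks of the
    zinc-finger hydrophobic core.  This scale is internal and is not
    comparable to external prediction-server scores.
    """
    score = 1.0
    if g2[9] in "LIVMF":  # helix position 4 = offset 5 + 4 in the x12
        score += 0.5
    if any(c in "FYW" for c in protein[max(0, start - 3):start]):
        score += 0.5
    return score


def find_zf_domains(protein: str, min_confidence: float = 0.0) -> list[ZincFinger]:
    """Non-overlapping C2H2 finger matches, N->C, with helix residues.

    Returns an empty list when no finger is found; raises on empty or
    non-amino-acid input.
    """
    if not protein:
        raise ValueError("protein sequence is empty")
    protein = protein.upper()
    bad = set(protein) - AA_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid letters in protein: {sorted(bad)}")
    fingers: list[ZincFinger] = []
    for m in _ZF_RE.finditer(protein):
        g1, g2 = m.group(1), m.group(2)
        x12_start = m.start() + 1 + len(g1) + 1  # first residue after second C
        # helix position 1 is offset 6 into the 12-residue spacer, i.e. six
        # residues before the first coordinating histidine; position -1 is
        # the residue immediately before it.  For the classic Zif268
        # finger-2 anchor FQCRICMRNFSRSDHLTTHIRTH this reads -1=R 1=S 2=D
        # 3=H 4=L 5=T 6=T.
        helix = {-1: g2[5]}
        for p in range(1, 7):
            helix[p] = g2[5 + p]
        conf = _confidence(protein, m.start(), g1, g2)
        if conf < min_confidence:
            continue
        fingers.append(
            ZincFinger(
                index=len(fingers),
                span=(m.start(), m.end()),
                sequence=m.group(0),
                helix_residues=helix,
                confidence=conf,
            )
        )
    return fingers


def predict_pwm(array: ZincFingerArray,
                code: RecognitionCodeTable | None = None,
                cross_strand_pos2: bool = False,
                pseudocount: float = 0.25) -> PWM:
    """PWM predicted from the helix residues under the canonical model.

    Fingers are laid down antiparallel: the C-terminal finger's triplet
    forms the 5' end of the motif.  Within a finger the sense-strand
    triplet columns are the preferences of residues 6, 3 and -1 in that
    order.  With ``cross_strand_pos2`` each finger contributes a fourth
    column for the base 3'-adjacent to its triplet, modeled as the
    complement of residue 2's preference.
    """
    if not array.fingers:
        raise ValueError("zinc-finger array is empty; nothing to predict")
    if code is None:
        code = RecognitionCodeTable.default()
    cols: list[np.ndarray] = []
    for finger in reversed(array.fingers):
        res = finger.helix_residues
        cols.append(code.lookup(6, res[6]))
        cols.append(code.lookup(3, res[3]))
        cols.append(code.lookup(-1, res[-1]))
        if cross_strand_pos2:
            cols.append(code.lookup(2, res[2])[_COMPLEMENT_PERM])
    return PWM(f"{array.protein_id}_predicted", np.column_stack(cols),
               pseudocount=pseudocount)
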