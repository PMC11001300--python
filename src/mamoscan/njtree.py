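"""Distance-based protein phylogeny: p-distances, neighbor joining,
bootstrap split support.

Distances come from an existing alignment (pairwise gap deletion, with
an optional Poisson correction -ln(1-p) for multiple hits).  Trees are
built with the classical Saitou-Nei neighbor-joining algorithm; Q-matrix
ties are broken by the smallest (i, j) index pair, and negative limb
lengths are clamped to zero with the deficit moved to the sibling edge.
Bootstrap support resamples alignment columns with replacement and
reports, for each internal split of the full-data tree, the percentage
of replicate trees containing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from Bio import SeqIO

GAP_CHARS = set("-.")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match taxa count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode
    taxa: list[str]

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the lexicographically smallest taxon (so the set is
        invariant to taxon input order)."""
        ref = min(self.taxa)
        all_taxa = set(self.taxa)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below: set[str] = set()
            for child, _ in node.children:
                clade = walk(child)
                if 1 < len(clade) < len(all_taxa) - 1:
                    side = clade if ref not in clade else all_taxa - clade
                    out.add(frozenset(side))
                below |= clade
            return below

        walk(self.root)
        return out

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between all leaf pairs (additivity oracle hook)."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sides = []
            for child, blen in node.children:
                sub = {leaf: d + blen for leaf, d in walk(child).items()}
                sides.append(sub)
            for i in range(len(sides)):
                for j in range(i + 1, len(sides)):
                    for a, da in sides[i].items():
                        for b, db in sides[j].items():
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
            merged = {}
            for side in sides:
                merged.update(side)
            return merged

        walk(self.root)
        return dists

    def to_newick(self, include_support: bool = False) -> str:
        def fmt(node: TreeNode, blen: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, b) for c, b in node.children)
                label = ""
                if include_support and node.support is not None:
                    label = str(int(round(node.support)))
                body = f"({inner}){label}"
            return body if blen is None else f"{body}:{blen:.6f}"

        return fmt(self.root, None) + ";"


def read_alignment(source) -> dict[str, str]:
    """Aligned FASTA (path/handle) or an id->sequence mapping, validated."""
    if isinstance(source, Mapping):
        aln = {k: str(v).upper() for k, v in source.items()}
    else:
        aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")}
    if len(aln) < 2:
        raise ValueError("alignment needs at least two sequences")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must all have the same length")
    return aln


def p_distance(alignment, correction: str = "poisson") -> DistanceMatrix:
    """Pairwise mismatch fraction with per-pair gap deletion.

    ``correction``: "none" for the raw proportion, "poisson" for
    -ln(1 - p).  A pair with no shared ungapped site is an error.
    """
    if correction not in ("none", "poisson"):
        raise ValueError("correction must be 'none' or 'poisson'")
    aln = read_alignment(alignment)
    taxa = list(aln)
    seqs = [np.frombuffer(aln[t].encode(), dtype="S1") for t in taxa]
    gap = [np.isin(s, [b"-", b"."]) for s in seqs]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(gap[i] | gap[j])
            n_valid = int(valid.sum())
            if n_valid == 0:
                raise ValueError(
                    f"no shared ungapped sites between {taxa[i]} and {taxa[j]}"
                )
            p = float((seqs[i][valid] != seqs[j][valid]).sum()) / n_valid
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated distance between {taxa[i]} and {taxa[j]}; "
                        "use correction='none'"
                    )
                p = -np.log1p(-p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa, d)


def _argmin_q(q: np.ndarray) -> tuple[int, int]:
    """Index pair of the minimal Q entry, ties to the smallest (i, j)."""
    n = q.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = q[iu]
    k = int(np.argmin(vals))  # argmin returns the first minimum: row-major
    return int(iu[0][k]), int(iu[1][k])


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classical Saitou-Nei NJ; unrooted tree (trifurcating root node)."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d = dm.d.copy()
    active = list(range(n))  # indices into current d
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = _argmin_q(q)
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ai, aj = active[i], active[j]
        parent = TreeNode(children=[(nodes[ai], li), (nodes[aj], lj)])
        # distances from the new node to the remaining ones
        new_col = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d = np.vstack([d, new_col])
        new_col = np.append(new_col, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        new_index = d.shape[0] - 1
        active = [a for a in active if a not in (ai, aj)] + [new_index]
    # resolve the final three nodes around an unrooted central vertex
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lens = [la, lb, lc]
    for k in range(3):
        if lens[k] < 0:
            deficit = lens[k]
            lens[k] = 0.0
            others = [x for x in range(3) if x != k]
            lens[others[0]] += deficit / 2
            lens[others[1]] += deficit / 2
    root = TreeNode(children=[(nodes[a], lens[0]), (nodes[b], lens[1]),
                              (nodes[c], lens[2])])
    return PhyloTree(root, list(dm.taxa))


def _resample_alignment(aln: dict[str, str], rng: np.random.Generator) -> dict[str, str]:
    length = len(next(iter(aln.values())))
    idx = rng.integers(0, length, size=length)
    return {t: "".join(s[k] for k in idx) for t, s in aln.items()}


def bootstrap_support(alignment, n_reps: int = 2000, seed: int | None = None,
                      correction: str = "poisson") -> PhyloTree:
    """Full-data NJ tree with percent bootstrap support on internal edges.

    Replicate r resamples columns with the deterministic substream
    ``default_rng([seed, r])``, so results are reproducible bit-for-bit
    for a fixed seed regardless of execution order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    aln = read_alignment(alignment)
    tree = neighbor_joining(p_distance(aln, correction))
    ref_splits = tree.splits()
    counts = {s: 0 for s in ref_splits}
    base = 0 if seed is None else seed
    for rep in range(n_reps):
        rng = np.random.default_rng([base, rep])
        rep_aln = _resample_alignment(aln, rng)
        rep_tree = neighbor_joining(p_distance(rep_aln, correction))
        for s in rep_tree.splits():
            if s in counts:
                counts[s] += 1

    ref = min(tree.taxa)
    all_taxa = set(tree.taxa)

    def annotate(node: TreeNode) -> set[str]:
        if node.is_leaf:
            return {node.name}
        below: set[str] = set()
        for child, _ in node.children:
            clade = annotate(child)
            if 1 < len(clade) < len(all_taxa) - 1:
                side = clade if ref not in clade else all_taxa - clade
                key = frozenset(side)
                if key in counts:
                    child.support = 100.0 * counts[key] / n_reps
            below |= clade
        return below

    annotate(tree.root)
    return tree
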