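"""Genome similarity (S_G), guide tree, and sequence ordering.

S_G is a length-normalized pairwise similarity in [0, 1]: the summed bit
score of a non-redundant HSP subset for the pair, normalized by the
geometric mean of the two self-comparison scores,

    S_G(a, b) = score(a, b) / sqrt(score(a, a) * score(b, b)).

This guarantees S_G = 1 for identical sequences and S_G = 0 when no HSP
survives the e-value filter, and is symmetric. The guide tree is average-
linkage (UPGMA) hierarchical clustering on the distance 1 - S_G with fully
deterministic tie-breaking; it expresses similarity structure for ordering
tracks, not phylogeny. No tree is built for fewer than three sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pairalign import HitSet, Hsp
from .seqio import InputSet

OVERLAP_FRACTION = 0.5  # non-redundant HSP selection threshold


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def pair_score(hits: list[Hsp]) -> float:
    """Summed bit score of a greedily selected non-redundant HSP subset.

    HSPs are taken in descending bit score (ties by smaller qstart, then
    sstart); an HSP is skipped when its query or subject interval overlaps
    an already-accepted HSP by more than half of its own span.
    """
    accepted: list[Hsp] = []
    total = 0.0
    for h in sorted(hits, key=lambda h: (-h.bit_score, h.qstart, h.sstart)):
        qlen, slen = h.qend - h.qstart, h.send - h.sstart
        redundant = any(
            _overlap(h.qstart, h.qend, g.qstart, g.qend) > OVERLAP_FRACTION * qlen
            or _overlap(h.sstart, h.send, g.sstart, g.send) > OVERLAP_FRACTION * slen
            for g in accepted
        )
        if not redundant:
            accepted.append(h)
            total += h.bit_score
    return total


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of S_G values with unit diagonal."""

    ids: list[str]
    sg: np.ndarray  # shape (n, n), values in [0, 1]

    def value(self, a: str, b: str) -> float:
        return float(self.sg[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                fh.write(sid + "\t" + "\t".join(f"{v:.6f}" for v in self.sg[i]) + "\n")


def compute_sg(hits: HitSet, inputs: InputSet) -> SimilarityMatrix:
    """S_G for every pair, from a HitSet that includes all self-pairs."""
    ids = inputs.ids
    n = len(ids)
    self_scores = {}
    for sid in ids:
        s = pair_score(hits.get(sid, sid))
        if s <= 0:
            raise ValueError(
                f"sequence {sid!r} has zero self-comparison score; "
                "cannot normalize S_G"
            )
        self_scores[sid] = s
    sg = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = pair_score(hits.get(ids[i], ids[j]))
            val = s / np.sqrt(self_scores[ids[i]] * self_scores[ids[j]])
            sg[i, j] = sg[j, i] = min(1.0, max(0.0, val))
    return SimilarityMatrix(ids=ids, sg=sg)


# ---------------------------------------------------------------------------
# guide tree (UPGMA on 1 - S_G)

@dataclass
class TreeNode:
    height: float
    name: str | None = None  # leaf name, None for internal nodes
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.name is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [l for c in self.children for l in c.leaves()]

    @property
    def size(self) -> int:
        return len(self.leaves())

    def min_leaf(self) -> str:
        return min(self.leaves())


@dataclass
class GuideTree:
    root: TreeNode
    leaf_order: list[str]


def build_guide_tree(sim: SimilarityMatrix) -> GuideTree:
    """UPGMA tree on d = 1 - S_G with deterministic tie-breaking.

    Among tied minimum distances, the cluster pair whose (lexicographically
    smallest member id) pair sorts first is merged. At each internal node
    the child with the larger subtree is placed first; equal sizes are
    ordered by smallest leaf id. This makes ``leaf_order`` a pure function
    of the similarity matrix.
    """
    n = len(sim.ids)
    if n < 3:
        raise ValueError("no tree for fewer than three sequences")
    dist: dict[frozenset[int], float] = {}
    clusters: dict[int, TreeNode] = {}
    sizes: dict[int, int] = {}
    reps: dict[int, str] = {}
    for i, sid in enumerate(sim.ids):
        clusters[i] = TreeNode(height=0.0, name=sid)
        sizes[i] = 1
        reps[i] = sid
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = 1.0 - float(sim.sg[i, j])
    next_id = n
    while len(clusters) > 1:
        # deterministic choice: min distance, ties by sorted representative pair
        def sort_key(key: frozenset[int]) -> tuple:
            a, b = sorted(key, key=lambda c: reps[c])
            return (dist[key], reps[a], reps[b])

        best = min(dist.keys(), key=sort_key)
        i, j = sorted(best, key=lambda c: reps[c])
        d = dist[best]
        ci, cj = clusters.pop(i), clusters.pop(j)
        # child ordering: larger subtree first, ties by smaller leaf id
        kids = sorted([ci, cj], key=lambda c: (-c.size, c.min_leaf()))
        node = TreeNode(height=d / 2.0, children=kids)
        new = next_id
        next_id += 1
        # average-linkage update
        for k in list(clusters.keys()):
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((new, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        dist.pop(best)
        clusters[new] = node
        sizes[new] = sizes[i] + sizes[j]
        reps[new] = min(reps[i], reps[j])
    root = next(iter(clusters.values()))
    return GuideTree(root=root, leaf_order=root.leaves())


def _escape_label(name: str) -> str:
    return name.replace(" ", "_")


def _newick_node(node: TreeNode, parent_height: float) -> str:
    blen = max(0.0, parent_height - node.height)
    if node.is_leaf:
        return f"{_escape_label(node.name)}:{blen:.6g}"
    inner = ",".join(_newick_node(c, node.height) for c in node.children)
    return f"({inner}):{blen:.6g}"


def write_newick(tree: GuideTree) -> str:
    """Newick string with branch lengths equal to height differences."""
    root = tree.root
    if root.is_leaf:
        return f"{_escape_label(root.name)}:0;"
    inner = ",".join(_newick_node(c, root.height) for c in root.children)
    return f"({inner});"


def order_sequences(inputs: InputSet, tree: GuideTree | None) -> list[str]:
    """Display order: guide-tree leaf order, or input order when no tree."""
    if tree is None:
        return inputs.ids
    return list(tree.leaf_order)
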