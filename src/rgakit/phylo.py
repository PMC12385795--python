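"""Rooted protein trees: Jukes-Cantor distances, UPGMA, bootstrap, Newick.

Distances come from pre-aligned protein sequences. The observed mismatch
fraction p is computed with pairwise deletion (columns where either sequence
carries a gap are dropped for that pair) and corrected for multiple hits
with the 20-state Jukes-Cantor model,

    d = -(19/20) * ln(1 - (20/19) * p),

which is finite for p < 19/20 and saturates beyond. UPGMA (size-weighted
average linkage, merge height = pair distance / 2) produces a rooted
ultrametric tree; ties between merge candidates are broken on the
lexicographically smallest pair of leaf-label sets so trees are reproducible
across platforms. Clade supports come from a column-resampling bootstrap:
the support of a clade is the percentage of replicate trees containing the
same leaf set.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import AnnotationError

GAP = "-"
_JC_SCALE = 19.0 / 20.0


@dataclass(frozen=True)
class TreeNode:
    """A node of a rooted ultrametric tree (leaves at height 0)."""

    height: float
    label: str | None = None
    children: tuple["TreeNode", ...] = ()
    support: float | None = None  # percent, internal nodes only

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> frozenset[str]:
        if self.is_leaf():
            return frozenset({self.label})
        return frozenset().union(*(c.leaf_labels() for c in self.children))

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes, root included."""
        if self.is_leaf():
            return []
        out = [self.leaf_labels()]
        for child in self.children:
            out.extend(child.clades())
        return out


def p_distance(seq_a: str, seq_b: str) -> float:
    """Observed mismatch fraction under pairwise deletion of gap columns."""
    if len(seq_a) != len(seq_b):
        raise AnnotationError("aligned sequences must have equal length")
    compared = mismatches = 0
    for a, b in zip(seq_a, seq_b):
        if a == GAP or b == GAP:
            continue
        compared += 1
        mismatches += a != b
    if compared == 0:
        raise AnnotationError("no comparable (both non-gap) columns")
    return mismatches / compared


def jc_protein(p: float) -> float:
    """Jukes-Cantor corrected protein distance for mismatch fraction p."""
    if not 0 <= p < _JC_SCALE:
        raise AnnotationError(f"p = {p} outside [0, 19/20): distance saturated")
    return -_JC_SCALE * math.log1p(-p / _JC_SCALE)


def distance_matrix(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """All-pairs Jukes-Cantor distances from a pre-aligned protein FASTA."""
    labels = list(alignment)
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jc_protein(p_distance(alignment[labels[i]], alignment[labels[j]]))
            dist[i, j] = dist[j, i] = d
    return labels, dist


def upgma(labels: list[str], dist: np.ndarray) -> TreeNode:
    """Size-weighted average-linkage agglomeration of a distance matrix."""
    n = len(labels)
    if n < 2:
        raise AnnotationError("need >= 2 taxa")
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise AnnotationError("distance matrix must be square and symmetric")

    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    keys = {i: (labels[i],) for i in range(n)}  # sorted leaf tuples for ties
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    active = set(range(n))

    while len(active) > 1:
        best = min(
            (
                (d[frozenset((i, j))], *sorted((keys[i], keys[j])), i, j)
                for i in active
                for j in active
                if i < j
            ),
        )
        _, _, _, i, j = best
        height = d[frozenset((i, j))] / 2.0
        left, right = sorted((i, j), key=lambda k: keys[k])
        merged = TreeNode(height=height, children=(nodes[left], nodes[right]))
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        keys[next_id] = tuple(sorted(keys[i] + keys[j]))
        active -= {i, j}
        for k in active:
            d[frozenset((next_id, k))] = (
                sizes[i] * d[frozenset((i, k))] + sizes[j] * d[frozenset((j, k))]
            ) / (sizes[i] + sizes[j])
        active.add(next_id)
        next_id += 1

    return nodes[next_id - 1]


def build_tree(alignment: dict[str, str]) -> TreeNode:
    """UPGMA tree from a pre-aligned protein alignment."""
    labels, dist = distance_matrix(alignment)
    return upgma(labels, dist)


def bootstrap_supports(
    alignment: dict[str, str], n_reps: int = 1000, seed: int = 0
) -> TreeNode:
    """Attach column-resampling bootstrap supports to the UPGMA tree.

    Each replicate resamples alignment columns with replacement and rebuilds
    the tree; a clade's support is the percentage of valid replicates whose
    tree contains the same leaf set. Replicates where some pair has no
    comparable columns (or a saturated distance) are skipped with a warning
    and removed from the denominator.
    """
    if n_reps < 1:
        raise AnnotationError("n_reps must be >= 1")
    base = build_tree(alignment)
    labels = list(alignment)
    columns = np.array(
        [list(alignment[label]) for label in labels], dtype="U1"
    )  # taxa x columns
    n_cols = columns.shape[1]
    rng = np.random.default_rng(seed)

    counts = {clade: 0 for clade in base.clades()}
    valid = 0
    for _ in range(n_reps):
        sample = columns[:, rng.integers(0, n_cols, size=n_cols)]
        try:
            dist = _pairwise_jc(sample)
        except AnnotationError as exc:
            warnings.warn(f"bootstrap replicate skipped: {exc}")
            continue
        valid += 1
        for clade in upgma(labels, dist).clades():
            if clade in counts:
                counts[clade] += 1
    if valid == 0:
        raise AnnotationError("all bootstrap replicates were degenerate")

    def decorate(node: TreeNode) -> TreeNode:
        if node.is_leaf():
            return node
        return TreeNode(
            height=node.height,
            children=tuple(decorate(c) for c in node.children),
            support=100.0 * counts[node.leaf_labels()] / valid,
        )

    return decorate(base)


def _pairwise_jc(char_matrix: np.ndarray) -> np.ndarray:
    n = char_matrix.shape[0]
    gaps = char_matrix == GAP
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            compared = int(ok.sum())
            if compared == 0:
                raise AnnotationError("pair with no comparable columns")
            p = float((char_matrix[i, ok] != char_matrix[j, ok]).sum()) / compared
            dist[i, j] = dist[j, i] = jc_protein(p)
    return dist


def _quote(label: str) -> str:
    if re.search(r"[\s()\[\]{},;:']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: TreeNode) -> str:
    """Newick string with branch lengths and supports as internal labels."""

    def walk(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf():
            text = _quote(node.label)
        else:
            inner = ",".join(walk(c, node.height) for c in node.children)
            support = "" if node.support is None else f"{node.support:g}"
            text = f"({inner}){support}"
        if parent_height is None:
            return text
        return f"{text}:{parent_height - node.height:.10g}"

    return walk(tree, None) + ";"
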