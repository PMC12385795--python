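"""Physical and sequence-similarity clustering of RGAs.

Physical clusters are maximal runs of neighbouring genes on one chromosome
whose intergenic gaps (end of one gene to start of the next) are all within
a distance threshold, 10 kb by default; singletons are not clusters.

Sequence similarity is computed from global protein alignments (match +1,
mismatch -1, linear gap -2 by default) as matched columns over alignment
columns, and the resulting similarity matrix is cut into k groups by
average-linkage agglomeration on distance 1 - similarity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .model import AnnotationError, GeneModel

DEFAULT_CLUSTER_THRESHOLD_BP = 10_000


@dataclass(frozen=True)
class PhysicalCluster:
    chromosome: str
    members: tuple[str, ...]  # gene IDs sorted by start coordinate
    span: tuple[int, int]     # (min start, max end), 1-based inclusive


@dataclass(frozen=True)
class SimilarityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, unit diagonal, fractions in [0, 1]


def physical_clusters(
    genes: Sequence[GeneModel],
    threshold_bp: int = DEFAULT_CLUSTER_THRESHOLD_BP,
) -> list[PhysicalCluster]:
    """Group genes whose neighbour gaps are all <= ``threshold_bp``.

    The gap between neighbours (after sorting by start within each
    chromosome) is ``start(next) - end(prev)``; the threshold boundary is
    inclusive. Runs of length 1 are discarded.
    """
    if threshold_bp < 0:
        raise AnnotationError("threshold_bp must be non-negative")
    clusters: list[PhysicalCluster] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chromosome, []).append(gene)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        run: list[GeneModel] = [ordered[0]]
        for gene in ordered[1:]:
            if gene.start - run[-1].end <= threshold_bp:
                run.append(gene)
            else:
                if len(run) >= 2:
                    clusters.append(_as_cluster(chrom, run))
                run = [gene]
        if len(run) >= 2:
            clusters.append(_as_cluster(chrom, run))
    return clusters


def _as_cluster(chrom: str, run: list[GeneModel]) -> PhysicalCluster:
    return PhysicalCluster(
        chromosome=chrom,
        members=tuple(g.gene_id for g in run),
        span=(min(g.start for g in run), max(g.end for g in run)),
    )


def clustered_gene_counts(
    clusters: Sequence[PhysicalCluster],
    class_of: Mapping[str, str] | None = None,
) -> tuple[int, Counter]:
    """Total clustered genes and a per-class breakdown (the reporting unit)."""
    members = [m for c in clusters for m in c.members]
    per_class: Counter = Counter()
    if class_of is not None:
        per_class.update(class_of.get(m, "NONE") for m in members)
    return len(members), per_class


def pairwise_similarity(
    sequences: Mapping[str, str],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> SimilarityMatrix:
    """All-pairs global-alignment similarity (matches / alignment columns)."""
    labels = tuple(sequences)
    if len(labels) < 2:
        raise AnnotationError("need >= 2 sequences")
    if any(not sequences[k] for k in labels):
        raise AnnotationError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap

    n = len(labels)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            alignment = aligner.align(sequences[labels[i]], sequences[labels[j]])[0]
            a, b = str(alignment[0]), str(alignment[1])
            matches = sum(x == y and x != "-" for x, y in zip(a, b))
            values[i, j] = values[j, i] = matches / len(a)
    return SimilarityMatrix(labels=labels, values=values)


def dendrogram_linkage(matrix: SimilarityMatrix) -> np.ndarray:
    """Average-linkage tree on distance = 1 - similarity (scipy linkage)."""
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    return hierarchy.linkage(squareform(dist, checks=False), method="average")


def dendrogram_clusters(
    matrix: SimilarityMatrix,
    k: int,
    superfamily_of: Mapping[str, str] | None = None,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Cut the average-linkage dendrogram into exactly k clusters.

    Returns a gene -> cluster-id assignment (ids renumbered 1..k by first
    appearance) and a composition table counting superfamilies per cluster
    when ``superfamily_of`` is given.
    """
    n = len(matrix.labels)
    if not 1 <= k <= n:
        raise AnnotationError(f"k must be in [1, {n}]")
    if n == 1:
        flat = np.array([1])
    else:
        flat = hierarchy.fcluster(dendrogram_linkage(matrix), t=k, criterion="maxclust")
    renumber: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for label, cid in zip(matrix.labels, flat):
        if cid not in renumber:
            renumber[cid] = len(renumber) + 1
        assignment[label] = renumber[cid]

    families = sorted({superfamily_of.get(l, "none") for l in matrix.labels}) \
        if superfamily_of else []
    rows = []
    for cid in range(1, max(assignment.values()) + 1):
        members = [l for l, c in assignment.items() if c == cid]
        row: dict[str, object] = {"cluster": cid, "n_genes": len(members)}
        for fam in families:
            row[fam] = sum(superfamily_of.get(m, "none") == fam for m in members)
        rows.append(row)
    return assignment, pd.DataFrame(rows)


def to_newick(matrix: SimilarityMatrix) -> str:
    """Export the average-linkage dendrogram as Newick with branch lengths."""
    link = dendrogram_linkage(matrix)
    tree = hierarchy.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return matrix.labels[node.id]
        left, right = node.get_left(), node.get_right()
        return (
            f"({walk(left)}:{node.dist - left.dist:.6g},"
            f"{walk(right)}:{node.dist - right.dist:.6g})"
        )

    return walk(tree) + ";"
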