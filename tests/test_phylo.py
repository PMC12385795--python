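import math

import dendropy
import numpy as np
import pytest

from rgakit.model import AnnotationError
from rgakit.phylo import (
    TreeNode,
    bootstrap_supports,
    build_tree,
    jc_protein,
    p_distance,
    to_newick,
    upgma,
)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("ARND", "ARND", 0.0),
        ("AR-ND", "AKCND", 0.25),  # gap column dropped, 1 mismatch in 4
        ("AAAA", "CCCC", 1.0),
    ],
)
def test_p_distance(a, b, expected):
    assert p_distance(a, b) == expected


def test_p_distance_errors():
    with pytest.raises(AnnotationError):
        p_distance("AA", "AAA")
    with pytest.raises(AnnotationError):
        p_distance("A-", "-A")  # no comparable columns


@pytest.mark.parametrize(
    "p, expected",
    [
        (0.0, 0.0),
        (0.1, -(19 / 20) * math.log(1 - (20 / 19) * 0.1)),
        (0.5, 0.7098536817),
    ],
)
def test_jc_closed_form(p, expected):
    assert jc_protein(p) == pytest.approx(expected, abs=1e-9)


def test_jc_saturation_and_inflation():
    with pytest.raises(AnnotationError):
        jc_protein(19 / 20)
    for p in np.linspace(0.01, 0.9, 30):
        assert jc_protein(p) >= p  # multiple-hit correction inflates


def test_jc_strictly_increasing_with_numeric_inverse():
    grid = np.linspace(0, 0.94, 200)
    values = [jc_protein(p) for p in grid]
    assert all(b > a for a, b in zip(values, values[1:]))
    # invert d = -(19/20) ln(1 - 20p/19) analytically and recover p
    for p in (0.05, 0.3, 0.7):
        d = jc_protein(p)
        p_hat = (19 / 20) * (1 - math.exp(-d / (19 / 20)))
        assert abs(p - p_hat) < 1e-12


def test_two_taxon_tree():
    tree = upgma(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
    assert to_newick(tree) == "(A:0.5,B:0.5);"


def test_three_taxon_hand_case():
    labels = ["A", "B", "C"]
    d = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
    tree = upgma(labels, d)
    assert tree.height == 2.0
    (ab, c) = sorted(tree.children, key=lambda n: len(n.leaf_labels()), reverse=True)
    assert ab.height == 1.0 and ab.leaf_labels() == {"A", "B"}
    assert c.label == "C"


def _brute_force_upgma(labels, dist):
    """Reference agglomeration: cluster distance recomputed as the plain
    mean over all original leaf-pair distances at every step."""
    index = {l: i for i, l in enumerate(labels)}
    clusters = {(l,): TreeNode(0.0, label=l) for l in labels}

    def cdist(ka, kb):
        return float(
            np.mean([dist[index[a], index[b]] for a in ka for b in kb])
        )

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            (cdist(ka, kb), *sorted((ka, kb)))
            for i, ka in enumerate(keys)
            for kb in keys[i + 1 :]
        )
        d, ka, kb = best
        node = TreeNode(d / 2.0, children=(clusters[ka], clusters[kb]))
        del clusters[ka], clusters[kb]
        clusters[tuple(sorted(ka + kb))] = node
    return next(iter(clusters.values()))


def _clade_heights(tree):
    out = {}
    stack = [tree]
    while stack:
        node = stack.pop()
        if not node.is_leaf():
            out[node.leaf_labels()] = node.height
            stack.extend(node.children)
    return out


def test_upgma_equals_brute_force_on_random_matrices():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(2, 7))
        labels = [f"t{i}" for i in range(n)]
        upper = rng.uniform(0.05, 2.0, size=(n, n))
        dist = np.triu(upper, 1)
        dist = dist + dist.T
        fast = _clade_heights(upgma(labels, dist))
        slow = _clade_heights(_brute_force_upgma(labels, dist))
        assert fast.keys() == slow.keys()
        for clade, height in fast.items():
            assert height == pytest.approx(slow[clade], rel=1e-9)


def test_upgma_heights_monotone_and_ultrametric_recovery():
    rng = np.random.default_rng(7)
    n = 8
    labels = [f"t{i}" for i in range(n)]
    # build a random ultrametric matrix from a random tree of merge heights
    heights = np.sort(rng.uniform(0.1, 1.0, size=n - 1))
    order = rng.permutation(n)
    dist = np.zeros((n, n))
    groups = [[labels[i]] for i in order]
    for h in heights:
        a = groups.pop(0)
        b = groups.pop(0)
        for x in a:
            for y in b:
                i, j = labels.index(x), labels.index(y)
                dist[i, j] = dist[j, i] = 2 * h
        groups.append(a + b)
    tree = upgma(labels, dist)
    for clade, height in _clade_heights(tree).items():
        for child_clade, child_height in _clade_heights(tree).items():
            if child_clade < clade:
                assert child_height <= height + 1e-12
    # reconstructed pairwise distances equal the generating matrix
    def tree_dist(node, a, b):
        clades = _clade_heights(node)
        return 2 * min(h for c, h in clades.items() if {a, b} <= c)

    for i in range(n):
        for j in range(i + 1, n):
            assert tree_dist(tree, labels[i], labels[j]) == pytest.approx(
                dist[i, j], rel=1e-9
            )


def test_non_symmetric_matrix_rejected():
    with pytest.raises(AnnotationError):
        upgma(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def _signal_alignment():
    rng = np.random.default_rng(13)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    fam1 = rng.choice(aa, size=150)
    fam2 = fam1.copy()
    flip = rng.random(150) < 0.5
    fam2[flip] = rng.choice(aa, size=int(flip.sum()))
    aln = {}
    for fam, consensus in (("x", fam1), ("y", fam2)):
        for m in range(3):
            seq = consensus.copy()
            noise = rng.random(150) < 0.05
            seq[noise] = rng.choice(aa, size=int(noise.sum()))
            aln[f"{fam}{m}"] = "".join(seq)
    return aln


def test_bootstrap_separated_families_and_determinism():
    aln = _signal_alignment()
    tree = bootstrap_supports(aln, n_reps=100, seed=3)
    supports = {
        clade: node_support
        for clade, node_support in _clade_supports(tree).items()
    }
    assert supports[frozenset({"x0", "x1", "x2"})] >= 95
    assert supports[frozenset({"y0", "y1", "y2"})] >= 95
    again = bootstrap_supports(aln, n_reps=100, seed=3)
    assert to_newick(again) == to_newick(tree)


def _clade_supports(tree):
    out = {}
    stack = [tree]
    while stack:
        node = stack.pop()
        if not node.is_leaf():
            if node.support is not None:
                out[node.leaf_labels()] = node.support
            stack.extend(node.children)
    return out


def test_two_taxon_bootstrap_support_100():
    tree = bootstrap_supports({"A": "ARNDAR", "B": "ARNDAA"}, n_reps=20, seed=0)
    assert tree.support == 100.0


def test_newick_round_trip_random_trees():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(2, 8))
        labels = [f"taxon {i}" for i in range(n)]  # spaces force quoting
        upper = rng.uniform(0.05, 2.0, size=(n, n))
        dist = np.triu(upper, 1)
        dist = dist + dist.T
        tree = upgma(labels, dist)
        text = to_newick(tree)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(labels)
        # leaf root-distances equal the UPGMA root height (ultrametric)
        parsed.calc_node_root_distances()
        for leaf in parsed.leaf_node_iter():
            assert leaf.root_distance == pytest.approx(tree.height, rel=1e-6)


def test_build_tree_from_alignment_matches_manual_pipeline():
    aln = _signal_alignment()
    tree = build_tree(aln)
    assert tree.leaf_labels() == set(aln)
    assert tree.height > 0
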