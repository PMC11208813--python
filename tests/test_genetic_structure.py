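import itertools
import math

import dendropy
import numpy as np
import pytest

from dompop import genetic_structure as gs
from dompop.types import DistanceMatrix
from conftest import random_binary_matrix


# ---------------------------------------------------------------------------
# Nei identity / distance

def test_nei_identity_hand_cases():
    assert gs.nei_identity([1, 1, 0, 1], [1, 1, 0, 1]) == pytest.approx(1.0)
    assert gs.nei_identity([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0
    assert gs.nei_identity([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.5)


def test_nei_identity_all_zero_profile_is_zero():
    assert gs.nei_identity([0, 0, 0], [1, 0, 1]) == 0.0


def test_nei_distance_closed_forms():
    assert gs.nei_distance(1.0) == pytest.approx(0.0)
    assert gs.nei_distance(0.5) == pytest.approx(math.log(2))
    assert gs.nei_distance(1.0, method="one_minus") == 0.0
    # identity 0 capped at -ln(1/(2L))
    capped = gs.nei_distance(np.array([0.0]), n_loci=103)
    assert capped[0] == pytest.approx(-math.log(1 / 206), abs=1e-9)


# ---------------------------------------------------------------------------
# UPGMA

def naive_upgma(labels, values):
    """Independent O(n^3) UPGMA oracle with dict bookkeeping (unweighted
    average over all member pairs, computed from the original matrix)."""
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters = {lab: frozenset([lab]) for lab in labels}
    merges = []
    refs = {lab: lab for lab in labels}
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [values[idx[x], idx[y]] for x in clusters[a] for y in clusters[b]]
            )
            key = (d, tuple(sorted((a, b))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        merges.append((refs[a], refs[b], float(d)))
        new = clusters.pop(a) | clusters.pop(b)
        name = min(a, b)
        clusters[name] = new
        refs[name] = len(merges) - 1
    return merges


def merge_heights_by_members(merges, leaf_labels):
    """Canonical (member-set -> height) map for topology comparison."""
    members = []
    out = {}
    for left, right, h in merges:
        s = set()
        for child in (left, right):
            s |= members[child] if isinstance(child, int) else {child}
        members.append(s)
        out[frozenset(s)] = h
    return out


def test_upgma_three_leaf_worked_example():
    dm = DistanceMatrix(
        ["A", "B", "C"],
        np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float),
    )
    tree = gs.upgma(dm)
    assert tree.merges[0] == ("A", "B", 2.0)
    assert tree.merges[1][2] == pytest.approx(6.0)


def test_upgma_equal_distances_tie_break_deterministic():
    n = 4
    labels = list("DACB")
    values = np.full((n, n), 3.0)
    np.fill_diagonal(values, 0.0)
    tree = gs.upgma(DistanceMatrix(labels, values))
    assert all(h == pytest.approx(3.0) for h in tree.heights())
    # lexicographic tie-break: first merge joins A and B
    assert set(tree.merges[0][:2]) == {"A", "B"}


@pytest.mark.parametrize("seed", range(20))
def test_upgma_matches_naive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 6
    labels = [f"L{i}" for i in range(n)]
    values = rng.uniform(1, 10, (n, n))
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    mine = gs.upgma(DistanceMatrix(labels, values)).merges
    oracle = naive_upgma(labels, values)
    assert merge_heights_by_members(mine, labels) == pytest.approx(
        merge_heights_by_members(oracle, labels)
    )


def test_upgma_invariant_to_label_order():
    rng = np.random.default_rng(3)
    labels = [f"L{i}" for i in range(7)]
    values = rng.uniform(1, 10, (7, 7))
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    tree1 = gs.upgma(DistanceMatrix(labels, values))
    perm = rng.permutation(7)
    tree2 = gs.upgma(
        DistanceMatrix([labels[i] for i in perm], values[np.ix_(perm, perm)])
    )
    assert merge_heights_by_members(tree1.merges, labels) == pytest.approx(
        merge_heights_by_members(tree2.merges, labels)
    )


def test_upgma_heights_match_scipy_average_linkage():
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(9)
    values = rng.uniform(1, 5, (8, 8))
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    tree = gs.upgma(DistanceMatrix([f"L{i}" for i in range(8)], values))
    Z = linkage(squareform(values), method="average")
    np.testing.assert_allclose(sorted(tree.heights()), sorted(Z[:, 2]))


def test_cophenetic_refeed_reproduces_topology():
    rng = np.random.default_rng(5)
    values = rng.uniform(1, 10, (6, 6))
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    labels = [f"L{i}" for i in range(6)]
    tree = gs.upgma(DistanceMatrix(labels, values))
    tree2 = gs.upgma(tree.cophenetic_matrix())
    assert merge_heights_by_members(tree.merges, labels) == pytest.approx(
        merge_heights_by_members(tree2.merges, labels)
    )


def test_cophenetic_correlation_ultrametric_is_one_and_oracle():
    rng = np.random.default_rng(7)
    values = rng.uniform(1, 10, (10, 10))
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    dm = DistanceMatrix([f"L{i}" for i in range(10)], values)
    tree = gs.upgma(dm)
    # ultrametric input: correlation with itself-implied distances is 1
    coph = tree.cophenetic_matrix()
    assert gs.cophenetic_correlation(gs.upgma(coph), coph) == pytest.approx(1.0)
    # naive double-loop oracle
    r = gs.cophenetic_correlation(tree, dm)
    xs, ys = [], []
    c = coph.values
    for i in range(10):
        for j in range(i + 1, 10):
            xs.append(values[i, j])
            ys.append(c[i, j])
    assert r == pytest.approx(np.corrcoef(xs, ys)[0, 1])


def test_cut_dendrogram_cases():
    dm = DistanceMatrix(
        ["A", "B", "C"],
        np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float),
    )
    tree = gs.upgma(dm)
    below = tree.cut(1.0)
    assert len(set(below.values())) == 3
    above = tree.cut(10.0)
    assert len(set(above.values())) == 1
    mid = tree.cut(4.0)
    assert mid["A"] == mid["B"] != mid["C"]


def test_newick_parses_with_correct_leaves_and_depths(default_dataset):
    dmat = gs.genetic_distance_matrix(default_dataset.matrix, "one_minus")
    tree = gs.upgma(dmat)
    parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    leaves = {t.label or t.taxon.label for t in parsed.leaf_node_iter()}
    assert leaves == set(default_dataset.matrix.individual_ids)
    # ultrametric: all root-to-leaf depths equal the root merge height
    depths = [leaf.distance_from_root() for leaf in parsed.leaf_node_iter()]
    assert max(depths) - min(depths) < 1e-4
    assert depths[0] == pytest.approx(tree.merges[-1][2], abs=1e-4)


# ---------------------------------------------------------------------------
# Mantel

def _random_distance(rng, n, labels=None):
    pts = rng.uniform(0, 10, (n, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels or [f"L{i}" for i in range(n)], d)


def test_mantel_self_correlation():
    rng = np.random.default_rng(2)
    d = _random_distance(rng, 10)
    res = gs.mantel_test(d, d, n_permutations=99, rng=np.random.default_rng(4))
    assert res.r == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 100)


def test_mantel_affine_invariance():
    rng = np.random.default_rng(6)
    d1 = _random_distance(rng, 9)
    d2 = DistanceMatrix(d1.labels, 3.5 * d1.values + 0.0)
    res = gs.mantel_test(d1, d2, n_permutations=49, rng=np.random.default_rng(1))
    assert res.r == pytest.approx(1.0)
    assert res.slope == pytest.approx(3.5)


def test_mantel_seed_reproducibility_and_r_squared():
    rng = np.random.default_rng(8)
    d1 = _random_distance(rng, 12)
    d2 = _random_distance(rng, 12)
    res1 = gs.mantel_test(d1, d2, 199, np.random.default_rng(42))
    res2 = gs.mantel_test(d1, d2, 199, np.random.default_rng(42))
    assert res1.p_value == res2.p_value
    assert res1.r_squared == pytest.approx(res1.r**2)


def test_mantel_matches_scikit_bio():
    from skbio.stats.distance import DistanceMatrix as SkbioDM, mantel

    rng = np.random.default_rng(12)
    d1 = _random_distance(rng, 15)
    d2 = _random_distance(rng, 15)
    res = gs.mantel_test(d1, d2, 999, np.random.default_rng(0))
    r_skbio, p_skbio, _ = mantel(
        SkbioDM(d1.values, d1.labels), SkbioDM(d2.values, d2.labels),
        method="pearson", permutations=999, alternative="greater",
    )
    assert res.r == pytest.approx(float(r_skbio), abs=1e-12)
    assert res.p_value == pytest.approx(float(p_skbio), abs=0.05)


def test_mantel_constant_matrix_rejected():
    n = 6
    values = np.full((n, n), 2.0)
    np.fill_diagonal(values, 0.0)
    d = DistanceMatrix([f"L{i}" for i in range(n)], values)
    rng = np.random.default_rng(1)
    other = _random_distance(rng, n, labels=d.labels)
    with pytest.raises(ValueError, match="constant"):
        gs.mantel_test(d, other, 99, rng)


def test_genetic_distance_matrix_roundtrip_labels(default_dataset):
    dm = gs.genetic_distance_matrix(default_dataset.matrix, "neg_log")
    assert dm.labels == default_dataset.matrix.individual_ids
    assert (dm.values >= 0).all()
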