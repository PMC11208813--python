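"""Individual-level genetic identity, UPGMA clustering, and Mantel tests.

Nei's normalized identity, specialized to individual 0/1 band profiles,
measures the cosine similarity of two band vectors; the dendrogram is
built by UPGMA on d = 1 - identity so that a similarity cut (e.g. "groups
that clustered at 0.58") maps to height 1 - 0.58 = 0.42.  The Mantel test
correlates two distance matrices over their off-diagonal pairs, with a
one-sided permutation null obtained by simultaneous row/column shuffling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import BinaryMarkerMatrix, DistanceMatrix

log = logging.getLogger("dompop")


# ---------------------------------------------------------------------------
# Nei identity / distance

def nei_identity(x, y) -> float:
    """Nei's normalized identity of two binary band profiles.

    I_xy = sum(x*y) / sqrt(sum(x^2) * sum(y^2)); all-zero profiles give 0
    (with a warning) rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profile length mismatch")
    sx, sy = float(x @ x), float(y @ y)
    if sx == 0 or sy == 0:
        log.warning("all-zero band profile in identity computation; identity set to 0")
        return 0.0
    return float((x @ y) / np.sqrt(sx * sy))


def identity_matrix(matrix: BinaryMarkerMatrix) -> np.ndarray:
    """Pairwise Nei identity among all individuals."""
    X = matrix.scores.astype(float)
    norms = np.sqrt((X**2).sum(axis=1))
    if (norms == 0).any():
        log.warning("individual(s) with no bands; their identities set to 0")
    safe = np.where(norms == 0, 1.0, norms)
    sim = (X @ X.T) / np.outer(safe, safe)
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, 0.0, 1.0)


def nei_distance(identity, n_loci: int | None = None, method: str = "neg_log"):
    """Convert identity to distance: -ln(I) (default) or 1 - I.

    identity 0 under ``neg_log`` is capped at -ln(1/(2L)) (needs ``n_loci``).
    """
    identity = np.asarray(identity, dtype=float)
    if method == "one_minus":
        return 1.0 - identity
    if method != "neg_log":
        raise ValueError(f"unknown distance method {method!r}")
    if (identity == 0).any():
        if n_loci is None:
            raise ValueError("capping -ln(0) requires n_loci")
        cap = -np.log(1.0 / (2 * n_loci))
        log.warning("identity 0 encountered; distance capped at %.3f", cap)
        with np.errstate(divide="ignore"):
            d = -np.log(identity)
        return np.minimum(d, cap)
    return -np.log(identity)


def genetic_distance_matrix(
    matrix: BinaryMarkerMatrix, method: str = "one_minus"
) -> DistanceMatrix:
    """Pairwise genetic DistanceMatrix from band profiles.

    ``one_minus`` (1 - identity) is used for the dendrogram so the height
    scale stays interpretable as 1 - similarity; ``neg_log`` is Nei's
    genetic distance, used for the isolation-by-distance Mantel test.
    """
    sim = identity_matrix(matrix)
    d = nei_distance(sim, n_loci=matrix.n_loci, method=method)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against fp noise
    return DistanceMatrix(list(matrix.individual_ids), d, f"nei_{method}")


def geographic_distance_matrix(labels, xy) -> DistanceMatrix:
    """Planar Euclidean distances (m) between trees (single UTM zone)."""
    xy = np.asarray(xy, dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(labels), d, "euclidean_geo")


# ---------------------------------------------------------------------------
# UPGMA

@dataclass
class Dendrogram:
    """Ultrametric UPGMA tree.

    ``merges`` is a list of (left, right, height) triples where left/right
    are either leaf labels or prior merge indices (int); heights are on the
    input distance scale (the merging distance itself, not half of it).
    """

    leaf_labels: list[str]
    merges: list[tuple[object, object, float]] = field(default_factory=list)

    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def _members(self) -> list[set[str]]:
        members: list[set[str]] = []
        for left, right, _ in self.merges:
            s: set[str] = set()
            for child in (left, right):
                s |= members[child] if isinstance(child, int) else {child}
            members.append(s)
        return members

    def cophenetic_matrix(self) -> DistanceMatrix:
        n = len(self.leaf_labels)
        idx = {lab: i for i, lab in enumerate(self.leaf_labels)}
        values = np.zeros((n, n))
        members = self._members()
        for k, (left, right, height) in enumerate(self.merges):
            a = members[left] if isinstance(left, int) else {left}
            b = members[right] if isinstance(right, int) else {right}
            for la in a:
                for lb in b:
                    values[idx[la], idx[lb]] = values[idx[lb], idx[la]] = height
        return DistanceMatrix(list(self.leaf_labels), values, "cophenetic")

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences (leaf height 0)."""
        node_height = {}

        def render(node) -> tuple[str, float]:
            if not isinstance(node, int):
                return str(node), 0.0
            left, right, height = self.merges[node]
            parts = []
            for child in (left, right):
                text, child_h = render(child)
                parts.append(f"{text}:{height - child_h:.6g}")
            return f"({','.join(parts)})", height

        text, _ = render(len(self.merges) - 1)
        return text + ";"

    def cut(self, height_threshold: float) -> dict[str, int]:
        """Group assignment: subtrees whose merges sit at height <= threshold
        form one group; groups are numbered 1.. in leaf order."""
        parent: dict[str, str] = {}

        def find(a):
            while parent.get(a, a) != a:
                parent[a] = parent.get(parent[a], parent[a])
                a = parent[a]
            return a

        members = self._members()
        for k, (left, right, height) in enumerate(self.merges):
            if height <= height_threshold:
                labs = sorted(members[k])
                root = labs[0]
                for lab in labs:
                    parent[find(lab)] = find(root)
        groups: dict[str, int] = {}
        next_id = 1
        for lab in self.leaf_labels:
            root = find(lab)
            if root not in groups:
                groups[root] = next_id
                next_id += 1
        return {lab: groups[find(lab)] for lab in self.leaf_labels}


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA with size-weighted average linkage.

    Merge height equals the merging distance itself.  Ties are broken by the
    lexicographically smallest (representative-label) pair, where a
    cluster's representative is its smallest leaf label, so output is
    invariant to input row order.
    """
    n = dist.n
    if n < 2:
        raise ValueError("need at least 2 leaves")
    labels = list(dist.labels)
    # active clusters: key -> (node ref, size, representative label)
    active: dict[int, tuple[object, int, str]] = {
        i: (labels[i], 1, labels[i]) for i in range(n)
    }
    D = {(i, j): float(dist.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    tree = Dendrogram(leaf_labels=labels)
    next_key = n
    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            d = D[(min(i, j), max(i, j))]
            rep = tuple(sorted((active[i][2], active[j][2])))
            cand = (d, rep, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        d, _, i, j = best
        node_i, size_i, rep_i = active.pop(i)
        node_j, size_j, rep_j = active.pop(j)
        tree.merges.append((node_i, node_j, d))
        new_ref = len(tree.merges) - 1
        for k in list(active):
            d_ik = D.pop((min(i, k), max(i, k)))
            d_jk = D.pop((min(j, k), max(j, k)))
            D[(min(next_key, k), max(next_key, k))] = (
                size_i * d_ik + size_j * d_jk
            ) / (size_i + size_j)
        active[next_key] = (new_ref, size_i + size_j, min(rep_i, rep_j))
        next_key += 1
    return tree


def cophenetic_correlation(tree: Dendrogram, dist: DistanceMatrix) -> float:
    """Pearson correlation between input and tree-implied (cophenetic)
    distances over off-diagonal pairs."""
    coph = tree.cophenetic_matrix()
    order = [coph.labels.index(lab) for lab in dist.labels]
    c = coph.values[np.ix_(order, order)]
    iu = np.triu_indices(dist.n, k=1)
    x, y = dist.values[iu], c[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant distance matrix: cophenetic correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Mantel test

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    slope: float
    intercept: float
    r_squared: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> MantelResult:
    """One-sided (greater) Mantel test of association between two distance
    matrices sharing labels; d2 is regressed on d1 for the reported line."""
    if d1.labels != d2.labels:
        order = [d2.labels.index(lab) for lab in d1.labels]
        d2 = DistanceMatrix(
            [d2.labels[i] for i in order],
            d2.values[np.ix_(order, order)],
            d2.metric_name,
        )
    n = d1.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 objects")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    y = d2.values[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    slope, intercept = np.polyfit(x, y, 1)

    rng = rng or np.random.default_rng()
    xc = (x - x.mean()) / x.std()
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = d2.values[np.ix_(perm, perm)][iu]
        r_perm = float(np.mean(xc * (yp - yp.mean()) / yp.std()))
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(
        r=r_obs,
        p_value=p,
        n_permutations=n_permutations,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r_obs**2,
    )
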