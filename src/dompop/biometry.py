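"""Fruit/diaspore biometry, allometric relations, and the trait distance
matrix for the trait-genetic Mantel test.

Multi-stemmed trees are collapsed to an equivalent single stem with the
root-sum-of-squares rule Ct = sqrt(sum ci^2) (the forestry convention that
preserves basal area), then DBH = Ct / pi.  Descriptive statistics follow
the desktop-statistics conventions: CV = 100*sd/mean with sample sd,
bias-corrected skewness G1 and excess kurtosis G2, and a Lilliefors
normality test with a seeded Monte Carlo null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .types import DiasporeRecord, DistanceMatrix, FruitRecord, TreeRecord


def total_circumference(circumferences, rule: str = "rss") -> float:
    """Equivalent single-stem circumference of a (possibly multi-stemmed) tree.

    ``rss`` (default): Ct = sqrt(sum ci^2); ``sum``: plain summation, kept
    for sensitivity analysis.
    """
    c = np.asarray(circumferences, dtype=float)
    if c.size == 0:
        raise ValueError("no circumference measurements")
    if rule == "rss":
        return float(np.sqrt((c**2).sum()))
    if rule == "sum":
        return float(c.sum())
    raise ValueError(f"unknown rule {rule!r}")


def dbh_from_circumference(ct: float) -> float:
    """DBH = Ct / pi (perimeter of a circle)."""
    return ct / math.pi


def lilliefors_mc(
    values, n_null: int = 10_000, rng: np.random.Generator | None = None
) -> float:
    """Lilliefors normality test p-value by Monte Carlo.

    The statistic is the KS distance of the standardized sample to N(0,1);
    the null distribution is simulated with ``n_null`` normal samples of
    the same size (mean/sd re-estimated each time), so the estimation step
    is accounted for.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 4:
        raise ValueError("Lilliefors test needs n >= 4")
    rng = rng or np.random.default_rng()

    def ks_stat(sample):
        z = (sample - sample.mean()) / sample.std(ddof=1)
        cdf = stats.norm.cdf(np.sort(z))
        ecdf_hi = np.arange(1, n + 1) / n
        ecdf_lo = np.arange(0, n) / n
        return max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo))

    d_obs = ks_stat(x)
    null = rng.standard_normal((n_null, n))
    z = (null - null.mean(axis=1, keepdims=True)) / null.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    cdf = stats.norm.cdf(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    d_null = np.maximum((ecdf_hi - cdf).max(axis=1), (cdf - ecdf_lo).max(axis=1))
    return float((1 + (d_null >= d_obs).sum()) / (1 + n_null))


@dataclass
class TraitSummary:
    n: int
    minimum: float
    maximum: float
    mean: float
    se: float
    cv_percent: float
    g1: float | None
    g2: float | None
    lilliefors_p: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def descriptive_stats(
    values, rng: np.random.Generator | None = None, n_null: int = 10_000
) -> TraitSummary:
    """Descriptive summary: mean, SE, CV%, skewness G1, excess kurtosis G2,
    and a Monte Carlo Lilliefors normality p-value."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("descriptive_stats needs n >= 4")
    mean = float(x.mean())
    if mean == 0:
        raise ValueError("mean is zero: CV undefined")
    sd = float(x.std(ddof=1))
    if sd == 0:
        return TraitSummary(n, float(x.min()), float(x.max()), mean,
                            0.0, 0.0, None, None, None)
    return TraitSummary(
        n=n,
        minimum=float(x.min()),
        maximum=float(x.max()),
        mean=mean,
        se=sd / math.sqrt(n),
        cv_percent=100.0 * sd / abs(mean),
        g1=float(stats.skew(x, bias=False)),
        g2=float(stats.kurtosis(x, bias=False, fisher=True)),
        lilliefors_p=lilliefors_mc(x, n_null=n_null, rng=rng),
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p
    from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("spearman needs two equal-length vectors, n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rs, p = stats.spearmanr(x, y)
    return float(rs), float(p)


@dataclass
class AllometryResult:
    tree_ids: list[str]
    ct: list[float]
    dbh: list[float]
    correlations: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return asdict(self)


def allometry(trees: list[TreeRecord], rule: str = "rss") -> AllometryResult:
    """Per-tree Ct and DBH plus Spearman correlations of DBH, total height
    and crown area."""
    ct = [total_circumference(t.stem_circumferences, rule=rule) for t in trees]
    dbh = [dbh_from_circumference(c) for c in ct]
    height = [t.total_height for t in trees]
    crown = [t.crown_area for t in trees]
    pairs = {
        "dbh_x_height": (dbh, height),
        "dbh_x_crown_area": (dbh, crown),
        "height_x_crown_area": (height, crown),
    }
    corrs = {}
    for name, (a, b) in pairs.items():
        rs, p = spearman(a, b)
        corrs[name] = {"rs": rs, "p": p}
    return AllometryResult(
        tree_ids=[t.tree_id for t in trees], ct=ct, dbh=dbh, correlations=corrs
    )


def fruit_frame(fruits: list[FruitRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tree_id": [f.tree_id for f in fruits],
            "length": [f.length for f in fruits],
            "diameter": [f.diameter for f in fruits],
            "fresh_mass": [f.fresh_mass for f in fruits],
            "pulp_yield": [f.pulp_yield for f in fruits],
        }
    )


def diaspore_frame(diaspores: list[DiasporeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tree_id": [d.tree_id for d in diaspores],
            "length": [d.length for d in diaspores],
            "diameter": [d.diameter for d in diaspores],
            "thickness": [d.thickness for d in diaspores],
            "fresh_mass": [d.fresh_mass for d in diaspores],
        }
    )


def trait_correlations(frame: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Spearman correlations among all numeric trait columns (pulp yield
    included only when present)."""
    cols = [
        c for c in frame.columns
        if c != "tree_id" and frame[c].notna().all()
    ]
    out = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rs, p = spearman(frame[a].to_numpy(), frame[b].to_numpy())
            out[f"{a}_x_{b}"] = {"rs": rs, "p": p}
    return out


def per_tree_means(frame: pd.DataFrame, columns=None) -> pd.DataFrame:
    cols = columns or [c for c in frame.columns if c != "tree_id"]
    cols = [c for c in cols if frame[c].notna().any()]
    return frame.groupby("tree_id", sort=True)[cols].mean()


def trait_euclidean(tree_means: pd.DataFrame, standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance on tree-level mean traits.

    Traits carry different units (mm vs g), so columns are z-standardized
    by default.  Trees with any missing trait are excluded with a warning;
    fewer than 4 remaining is an error.
    """
    means = tree_means.dropna(axis=0)
    if len(means) < len(tree_means):
        import logging

        logging.getLogger("dompop").warning(
            "excluded %d trees with missing traits", len(tree_means) - len(means)
        )
    if len(means) < 4:
        raise ValueError("fewer than 4 trees with complete traits")
    X = means.to_numpy(dtype=float)
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([str(i) for i in means.index], d, "euclidean_traits")
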