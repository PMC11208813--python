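"""Second-order neighbour density function (NDF) with Monte Carlo
complete-spatial-randomness (CSR) envelopes.

The NDF (O-ring statistic) for distance class (t_{k-1}, t_k] is the mean
number of neighbours per unit annulus area,

    NDF_k = (1/n) * sum_i #{j != i : t_{k-1} < d_ij <= t_k} / (pi t_k^2 - pi t_{k-1}^2),

computed without edge correction.  The CSR envelope is a pointwise rank
envelope from ``n_sims`` uniform patterns in the same window, using the
same uncorrected statistic, so the test is valid by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import ValidationError


Window = tuple[float, float, float, float]  # xmin, xmax, ymin, ymax


def bounding_window(points, pad: float = 1.0) -> Window:
    """Axis-aligned bounding rectangle of the points, padded (default 1 m)."""
    pts = np.asarray(points, dtype=float)
    return (
        float(pts[:, 0].min() - pad),
        float(pts[:, 0].max() + pad),
        float(pts[:, 1].min() - pad),
        float(pts[:, 1].max() + pad),
    )


def _annulus_areas(bounds: np.ndarray) -> np.ndarray:
    lower = np.concatenate(([0.0], bounds[:-1]))
    return math.pi * (bounds**2 - lower**2)


def ndf(points, class_bounds, window: Window) -> np.ndarray:
    """Per-class neighbour density (neighbours per m^2); no edge correction."""
    pts = np.asarray(points, dtype=float)
    bounds = np.asarray(class_bounds, dtype=float)
    if len(pts) < 2:
        raise ValidationError("NDF needs at least 2 points")
    xmin, xmax, ymin, ymax = window
    inside = (
        (pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
        & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax)
    )
    if not inside.all():
        raise ValidationError("point outside the analysis window")
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(len(pts), k=1)
    pair_d = d[iu]
    lower = np.concatenate(([0.0], bounds[:-1]))
    counts = np.array(
        [((pair_d > lo) & (pair_d <= hi)).sum() for lo, hi in zip(lower, bounds)]
    )
    # each unordered pair contributes a neighbour to both endpoints
    return 2.0 * counts / len(pts) / _annulus_areas(bounds)


def csr_envelope(
    n: int,
    window: Window,
    class_bounds,
    n_sims: int = 499,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise rank envelope of the NDF under CSR.

    Per class, the k-th smallest and k-th largest of the simulated values
    with k = ceil(alpha/2 * (n_sims + 1)).
    """
    if n_sims < 2 / alpha:
        raise ValidationError("n_sims too small to resolve the envelope at this alpha")
    rng = rng or np.random.default_rng()
    xmin, xmax, ymin, ymax = window
    bounds = np.asarray(class_bounds, dtype=float)
    sims = np.empty((n_sims, len(bounds)))
    for s in range(n_sims):
        pts = np.column_stack(
            (rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n))
        )
        sims[s] = ndf(pts, bounds, window)
    k = math.ceil(alpha / 2 * (n_sims + 1))
    order = np.sort(sims, axis=0)
    return order[k - 1], order[n_sims - k]


@dataclass
class SpatialPattern:
    class_bounds: list[float]
    ndf_values: list[float]
    envelope_lower: list[float]
    envelope_upper: list[float]
    classification: list[str]

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def classify(values, lower, upper) -> list[str]:
    """Per-class label: above envelope -> aggregated, below -> uniform,
    inside -> random."""
    out = []
    for v, lo, hi in zip(values, lower, upper):
        out.append("aggregated" if v > hi else "uniform" if v < lo else "random")
    return out


def analyze_spatial(
    points,
    class_bounds=tuple(range(10, 101, 10)),
    n_sims: int = 499,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
    window: Window | None = None,
) -> SpatialPattern:
    """Full correlogram: observed NDF, CSR envelope, per-class labels."""
    pts = np.asarray(points, dtype=float)
    window = window or bounding_window(pts)
    values = ndf(pts, class_bounds, window)
    lower, upper = csr_envelope(len(pts), window, class_bounds, n_sims, alpha, rng)
    return SpatialPattern(
        class_bounds=[float(b) for b in class_bounds],
        ndf_values=[float(v) for v in values],
        envelope_lower=[float(v) for v in lower],
        envelope_upper=[float(v) for v in upper],
        classification=classify(values, lower, upper),
    )
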