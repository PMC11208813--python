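"""Shared domain types for the dominant-marker population analysis pipeline.

The central object is :class:`BinaryMarkerMatrix`, an individuals x loci 0/1
band-score matrix with a locus -> primer grouping, as produced by scoring
dominant multilocus fingerprints (ISSR/RAPD) on a gel.  All downstream
statistics consume either this matrix, the tree table
(:class:`TreeRecord`), or pairwise :class:`DistanceMatrix` objects.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml


class ValidationError(ValueError):
    """Raised when an input object or file violates a structural invariant."""


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for a named pipeline stage.

    Streams derived from the same root seed but different stage names are
    statistically independent, so skipping or re-running one stage never
    perturbs another's numbers.
    """
    digest = hashlib.sha256(stage.encode()).digest()
    stage_key = int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((int(root_seed), stage_key)))


@dataclass
class BinaryMarkerMatrix:
    """Individuals x loci binary band scores (1 = band present).

    Invariants: scores are exactly 0/1, labels are unique, every locus maps
    to exactly one primer, and at least two individuals are present.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    primer_of_locus: dict[str, str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        n, L = self.scores.shape
        if n < 2:
            raise ValidationError("marker matrix needs at least 2 individuals")
        if len(self.individual_ids) != n or len(self.locus_ids) != L:
            raise ValidationError("label lists do not match score dimensions")
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate individual labels")
        if len(set(self.locus_ids)) != L:
            raise ValidationError("duplicate locus labels")
        bad = ~np.isin(self.scores, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"non-binary score at individual {self.individual_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r}: {self.scores[i, j]!r}"
            )
        missing = [l for l in self.locus_ids if l not in self.primer_of_locus]
        if missing:
            raise ValidationError(f"loci without a primer assignment: {missing[:5]}")
        self.scores = self.scores.astype(np.int8)

    @property
    def n_individuals(self) -> int:
        return self.scores.shape[0]

    @property
    def n_loci(self) -> int:
        return self.scores.shape[1]

    def band_frequencies(self) -> np.ndarray:
        """Per-locus fraction of individuals showing the band."""
        return self.scores.mean(axis=0)

    def primer_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for locus in self.locus_ids:
            groups.setdefault(self.primer_of_locus[locus], []).append(locus)
        return groups


@dataclass
class TreeRecord:
    """One surveyed tree: planar UTM coordinates (m), stem circumferences at
    breast height (cm), total height (m), crown area (m^2), fruiting flag."""

    tree_id: str
    x: float
    y: float
    stem_circumferences: list[float]
    total_height: float
    crown_area: float
    fruiting: bool

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(f"tree {self.tree_id}: non-finite coordinates")
        if not self.stem_circumferences:
            raise ValidationError(f"tree {self.tree_id}: no stem circumference")
        if any(c <= 0 for c in self.stem_circumferences):
            raise ValidationError(f"tree {self.tree_id}: non-positive circumference")
        if self.total_height <= 0:
            raise ValidationError(f"tree {self.tree_id}: non-positive height")
        if self.crown_area < 0:
            raise ValidationError(f"tree {self.tree_id}: negative crown area")


@dataclass
class FruitRecord:
    """One fruit's calliper/balance measurements from a mother tree."""

    tree_id: str
    length: float  # mm
    diameter: float  # mm
    fresh_mass: float  # g
    pulp_yield: float | None = None  # g, optional

    def __post_init__(self) -> None:
        for name in ("length", "diameter", "fresh_mass"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"fruit of {self.tree_id}: non-positive {name}")


@dataclass
class DiasporeRecord:
    """One diaspore (endocarp + seed, the dispersal unit)."""

    tree_id: str
    length: float  # mm
    diameter: float  # mm
    thickness: float  # mm
    fresh_mass: float  # g

    def __post_init__(self) -> None:
        for name in ("length", "diameter", "thickness", "fresh_mass"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"diaspore of {self.tree_id}: non-positive {name}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = "distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValidationError("distance matrix has non-finite entries")
        if (self.values < 0).any():
            raise ValidationError("distance matrix has negative entries")
        if not np.allclose(self.values, self.values.T, atol=0, rtol=0):
            raise ValidationError("distance matrix is not exactly symmetric")
        if np.diag(self.values).any():
            raise ValidationError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy condensed) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


_DEFAULT_CLASSES = tuple(float(t) for t in range(10, 101, 10))


@dataclass
class McmcSettings:
    burn_in: int = 5_000
    iterations: int = 10_000
    n_runs: int = 5
    k_min: int = 1
    k_max: int = 4


@dataclass
class BottleneckSettings:
    models: tuple[str, ...] = ("IAM", "SMM")
    n_coalescent_sims: int = 1_000


@dataclass
class AnalysisConfig:
    """All tunables of the pipeline, with one root RNG seed.

    Every stochastic stage draws from ``stage_rng(rng_seed, stage_name)`` so
    stages are reproducible in isolation.  MCMC defaults are scaled down from
    the desktop-program settings the field typically uses (500k iterations);
    full settings remain configurable.
    """

    rng_seed: int = 0
    distance_classes: tuple[float, ...] = _DEFAULT_CLASSES
    n_csr_sims: int = 499
    envelope_alpha: float = 0.01
    mantel_permutations: int = 1_000
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    bottleneck: BottleneckSettings = field(default_factory=BottleneckSettings)
    dendrogram_cut: float = 0.58  # on the Nei-identity (similarity) scale

    def __post_init__(self) -> None:
        if not 0 < self.envelope_alpha < 1:
            raise ValidationError("envelope_alpha must be in (0,1)")
        for name in ("n_csr_sims", "mantel_permutations"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if list(self.distance_classes) != sorted(set(self.distance_classes)):
            raise ValidationError("distance classes must be strictly increasing")
        if self.mcmc.k_min < 1 or self.mcmc.k_min > self.mcmc.k_max:
            raise ValidationError("invalid K range")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mcmc = McmcSettings(**raw.pop("mcmc", {}))
        bott = raw.pop("bottleneck", {})
        if "models" in bott:
            bott["models"] = tuple(bott["models"])
        bottleneck = BottleneckSettings(**bott)
        if "distance_classes" in raw:
            raw["distance_classes"] = tuple(raw["distance_classes"])
        return cls(mcmc=mcmc, bottleneck=bottleneck, **raw)

    def to_dict(self) -> dict:
        return asdict(self)
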