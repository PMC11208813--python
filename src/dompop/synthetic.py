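"""Synthetic-data generator for the full pipeline.

Emulates a small, spatially aggregated tree population scored with
dominant markers: ~53 trees from a Thomas cluster process of which 23 are
fruiting and genotyped, ~103 biallelic dominant loci grouped into 10
primers, two latent ancestral clusters under an F-model (cluster allele
frequencies drawn from a Beta centred on an ancestral frequency with
variance set by a drift parameter), weak spatial-ancestry coupling
(isolation by distance), fruit/diaspore traits with a configurable
genetic component, and an optional Wright-Fisher bottleneck history.

All outputs are reproducible bit-for-bit given (scenario, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .types import BinaryMarkerMatrix, DiasporeRecord, FruitRecord, TreeRecord, stage_rng

log = logging.getLogger("dompop")

# locus counts per primer emulating a ten-primer ISSR panel totalling 103
DEFAULT_PRIMER_PARTITION = (7, 10, 10, 9, 11, 12, 12, 11, 12, 9)

# trait means and CVs (CV as a fraction) emulating field fruit biometry
DEFAULT_FRUIT_TRAITS = {
    "length": (31.12, 0.1005),
    "diameter": (28.68, 0.1203),
    "fresh_mass": (15.56, 0.2969),
}
DEFAULT_DIASPORE_TRAITS = {
    "length": (19.27, 0.0908),
    "diameter": (13.95, 0.0939),
    "thickness": (11.14, 0.1079),
    "fresh_mass": (2.28, 0.3405),
}


@dataclass
class BottleneckScenario:
    """Forward Wright-Fisher demographic history for one population."""

    n_before: int = 500
    n_after: int = 10
    generations_after: int = 5
    # low rate keeps loci in the single-origin regime the equilibrium
    # (coalescent, k-conditioned) null assumes
    mutation_rate: float = 2e-5

    def __post_init__(self) -> None:
        if self.generations_after > 0 and self.n_after >= self.n_before:
            raise ValueError("bottleneck requires N_after < N_before")


@dataclass
class SimulationScenario:
    n_trees: int = 53
    n_fruiting: int = 23
    n_loci: int = 103
    primer_partition: tuple[int, ...] = DEFAULT_PRIMER_PARTITION
    k_true: int = 2
    drift: float = 0.2  # F-model divergence among clusters, in (0,1)
    p_anc_range: tuple[float, float] = (0.1, 0.5)  # ancestral presence-allele freq
    admixture_alpha: float = 0.05
    balanced_hard_assignment: bool = False
    window: tuple[float, float, float, float] = (0.0, 100.0, 0.0, 100.0)
    n_parents: int = 5
    dispersal_sd: float = 5.0  # m
    spatial_genetic_coupling: float = 0.6  # prob. ancestry follows spatial parent
    bottleneck: BottleneckScenario | None = None
    fruit_traits: dict = field(default_factory=lambda: dict(DEFAULT_FRUIT_TRAITS))
    diaspore_traits: dict = field(default_factory=lambda: dict(DEFAULT_DIASPORE_TRAITS))
    genetic_weight: float = 0.35  # share of the per-tree trait latent from genotype
    tree_effect: float = 0.5  # loading of the per-tree latent on each measurement
    fruit_size_effect: float = 0.6  # loading of the shared per-fruit latent
    mean_fruits_per_tree: float = 9.0
    max_fruits_per_tree: int = 37
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fruiting > self.n_trees:
            raise ValueError("n_fruiting cannot exceed n_trees")
        if not 0 < self.drift < 1:
            raise ValueError("drift must be in (0,1)")
        if self.dispersal_sd <= 0:
            raise ValueError("dispersal sd must be positive")
        if self.n_parents > self.n_trees:
            raise ValueError("more cluster parents than trees")
        if sum(self.primer_partition) != self.n_loci:
            raise ValueError("primer partition must sum to n_loci")
        for table in (self.fruit_traits, self.diaspore_traits):
            for name, (mean, cv) in table.items():
                if cv <= 0:
                    raise ValueError(f"trait {name}: CV must be positive")
        if not 0 <= self.genetic_weight <= 1:
            raise ValueError("genetic_weight must be in [0,1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _locus_labels(partition) -> tuple[list[str], dict[str, str]]:
    locus_ids, primer_of_locus = [], {}
    counter = 0
    for g, size in enumerate(partition, start=1):
        primer = f"P{g:02d}"
        for _ in range(size):
            counter += 1
            locus = f"{primer}:L{counter:03d}"
            locus_ids.append(locus)
            primer_of_locus[locus] = primer
    return locus_ids, primer_of_locus


# ---------------------------------------------------------------------------
# coordinates

def simulate_coordinates(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    return_parents: bool = False,
):
    """Thomas cluster process: uniform parent points, Gaussian offspring
    displacement, resampling of offspring falling outside the window."""
    rng = rng or stage_rng(scenario.seed, "coordinates")
    xmin, xmax, ymin, ymax = scenario.window
    if xmin >= xmax or ymin >= ymax:
        raise ValueError("degenerate window")
    parents = np.column_stack(
        (
            rng.uniform(xmin, xmax, scenario.n_parents),
            rng.uniform(ymin, ymax, scenario.n_parents),
        )
    )
    coords = np.empty((scenario.n_trees, 2))
    parent_idx = rng.integers(0, scenario.n_parents, scenario.n_trees)
    for i, pi in enumerate(parent_idx):
        while True:
            pt = parents[pi] + rng.normal(0, scenario.dispersal_sd, 2)
            if xmin <= pt[0] <= xmax and ymin <= pt[1] <= ymax:
                coords[i] = pt
                break
    if return_parents:
        return coords, parent_idx
    return coords


# ---------------------------------------------------------------------------
# genotypes

def _draw_cluster_frequencies(scenario, rng, n_loci):
    """F-model: uniform ancestral presence-allele frequency; cluster
    frequencies ~ Beta centred on it with variance set by the drift."""
    p_anc = rng.uniform(*scenario.p_anc_range, n_loci)
    F = scenario.drift
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    P = rng.beta(a, b, size=(scenario.k_true, n_loci))
    return p_anc, np.clip(P, 1e-6, 1 - 1e-6)


def _draw_admixture(scenario, rng, n, base_cluster=None):
    K = scenario.k_true
    if K == 1:
        return np.ones((n, 1))
    if scenario.balanced_hard_assignment:
        Q = np.zeros((n, K))
        Q[np.arange(n), np.arange(n) % K] = 1.0
        return Q
    Q = rng.dirichlet(np.full(K, scenario.admixture_alpha), size=n)
    if base_cluster is not None:
        # rotate components so each individual's dominant cluster lands on
        # its spatially inherited base cluster (isolation-by-distance knob)
        for i, c in enumerate(base_cluster):
            j = int(np.argmax(Q[i]))
            if j != c:
                Q[i, [j, c]] = Q[i, [c, j]]
    return Q


def simulate_genotypes(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    individual_ids=None,
    base_cluster=None,
):
    """Dominant biallelic genotypes for the genotyped (fruiting) individuals.

    Per locus, an individual's presence-allele frequency is Q @ P; two
    allele copies are drawn Bernoulli and the band shows iff at least one
    copy carries the presence allele (dominance applied at sampling, so the
    HWE square-root estimator stays a genuine estimator).  Loci whose band
    is absent in every sampled individual are unobservable on a gel and are
    redrawn, mirroring how dominant loci come to be scored at all.

    Returns (matrix, truth) where truth holds Q_true, cluster frequencies
    and ancestral frequencies.
    """
    rng = rng or stage_rng(scenario.seed, "genotypes")
    n = scenario.n_fruiting
    if individual_ids is None:
        individual_ids = [f"T{i + 1:02d}" for i in range(n)]
    Q = _draw_admixture(scenario, rng, n, base_cluster=base_cluster)
    L = scenario.n_loci
    p_anc = np.empty(L)
    P = np.empty((scenario.k_true, L))
    bands = np.empty((n, L), dtype=np.int8)
    filled = 0
    attempts = 0
    while filled < L:
        attempts += 1
        if attempts > 200:
            raise RuntimeError("could not draw enough observable loci")
        pa, Pk = _draw_cluster_frequencies(scenario, rng, L)
        p_ind = Q @ Pk  # n x L presence-allele frequency per individual
        copies = rng.random((2, n, L)) < p_ind
        b = copies.any(axis=0).astype(np.int8)
        observable = b.any(axis=0)
        take = min(int(observable.sum()), L - filled)
        sel = np.flatnonzero(observable)[:take]
        sl = slice(filled, filled + take)
        p_anc[sl], P[:, sl], bands[:, sl] = pa[sel], Pk[:, sel], b[:, sel]
        filled += take
    locus_ids, primer_of_locus = _locus_labels(scenario.primer_partition)
    matrix = BinaryMarkerMatrix(list(individual_ids), locus_ids, primer_of_locus, bands)
    truth = {"Q_true": Q, "cluster_freqs": P, "p_ancestral": p_anc}
    return matrix, truth


# ---------------------------------------------------------------------------
# bottleneck population

def simulate_bottleneck_population(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    require_polymorphic: bool = True,
) -> BinaryMarkerMatrix:
    """Forward Wright-Fisher simulation per biallelic locus.

    Loci start at the symmetric mutation-drift stationary distribution
    Beta(theta, theta) with theta = 4*N*u, burn in for 2N generations at
    N_before, then (if a bottleneck block is present) collapse to N_after
    for ``generations_after`` generations.  Individuals are sampled by
    infinite-gamete draws from the final allele frequency; dominance is
    applied per individual.  With no bottleneck block the population is an
    equilibrium control.

    Rare alleles are lost in the collapse faster than heterozygosity
    declines, producing the heterozygosity-excess signature downstream.
    """
    rng = rng or stage_rng(scenario.seed, "bottleneck_population")
    demo = scenario.bottleneck or BottleneckScenario(
        n_before=500, n_after=500, generations_after=0
    )
    u = demo.mutation_rate
    theta = 4 * demo.n_before * u

    def evolve(n_loci_batch: int) -> np.ndarray:
        x = rng.beta(theta, theta, n_loci_batch)
        for N, gens in ((demo.n_before, 2 * demo.n_before),
                        (demo.n_after, demo.generations_after)):
            for _ in range(gens):
                x = x * (1 - u) + (1 - x) * u
                x = rng.binomial(2 * N, x) / (2 * N)
        return x

    n = scenario.n_fruiting
    individual_ids = [f"T{i + 1:02d}" for i in range(n)]
    collected: list[np.ndarray] = []
    attempts = 0
    while sum(c.shape[1] for c in collected) < scenario.n_loci:
        attempts += 1
        if attempts > 200:
            raise RuntimeError("could not collect enough polymorphic loci")
        x = evolve(scenario.n_loci)
        # random labelling of which allele is the band-presence allele
        flip = rng.random(scenario.n_loci) < 0.5
        p = np.where(flip, 1 - x, x)
        copies = rng.random((2, n, scenario.n_loci)) < p
        bands = copies.any(axis=0).astype(np.int8)
        if require_polymorphic:
            f = bands.mean(axis=0)
            bands = bands[:, (f > 0) & (f < 1)]
        collected.append(bands)
    scores = np.concatenate(collected, axis=1)[:, : scenario.n_loci]
    locus_ids, primer_of_locus = _locus_labels(scenario.primer_partition)
    return BinaryMarkerMatrix(individual_ids, locus_ids, primer_of_locus, scores)


def equilibrium_scenario(seed: int = 0, **kwargs) -> SimulationScenario:
    """Mutation-drift-equilibrium control: same demography, no size change."""
    return SimulationScenario(
        seed=seed, bottleneck=BottleneckScenario(500, 500, 0), **kwargs
    )


def severe_bottleneck_scenario(seed: int = 0, **kwargs) -> SimulationScenario:
    """Recent severe decline: N 500 -> 10 for 5 generations."""
    return SimulationScenario(
        seed=seed, bottleneck=BottleneckScenario(500, 10, 5), **kwargs
    )


# ---------------------------------------------------------------------------
# traits and allometry

def _positive_lognormal_like(rng, mean, cv, z, max_tries: int = 200):
    """mean * (1 + cv * z), resampling the standard-normal residual of any
    non-positive draws (bounded retries)."""
    values = mean * (1 + cv * z)
    tries = 0
    while (values <= 0).any():
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not draw positive trait values")
        bad = values <= 0
        values[bad] = mean * (1 + cv * rng.standard_normal(bad.sum()))
    return values


def simulate_traits(
    scenario: SimulationScenario,
    matrix: BinaryMarkerMatrix,
    rng: np.random.Generator | None = None,
):
    """Fruit and diaspore measurement tables for the fruiting trees.

    Each tree carries a latent quality u = w*g + sqrt(1-w^2)*eta, where g
    is the standardized band-count of its genotype and w the genetic
    weight; each fruit adds a shared size latent; each measurement adds
    independent noise.  Pulp yield is a noisy fraction of fruit fresh mass.
    """
    rng = rng or stage_rng(scenario.seed, "traits")
    n = matrix.n_individuals
    band_count = matrix.scores.sum(axis=1).astype(float)
    sd = band_count.std()
    g = (band_count - band_count.mean()) / sd if sd > 0 else np.zeros(n)
    w = scenario.genetic_weight
    u = w * g + np.sqrt(1 - w**2) * rng.standard_normal(n)

    mean_extra = scenario.mean_fruits_per_tree - 1
    r_disp = 2.0
    counts = 1 + rng.negative_binomial(r_disp, r_disp / (r_disp + mean_extra), n)
    counts = np.clip(counts, 1, scenario.max_fruits_per_tree)

    a = scenario.tree_effect
    b = scenario.fruit_size_effect
    c = np.sqrt(max(1 - a**2 - b**2, 0.0))

    fruits: list[FruitRecord] = []
    diaspores: list[DiasporeRecord] = []
    for i, tree_id in enumerate(matrix.individual_ids):
        m = int(counts[i])
        v = rng.standard_normal(m)  # shared per-fruit size latent

        def draw(table):
            cols = {}
            for name, (mean, cv) in table.items():
                z = a * u[i] + b * v + c * rng.standard_normal(m)
                cols[name] = _positive_lognormal_like(rng, mean, cv, z)
            return cols

        fr = draw(scenario.fruit_traits)
        pulp_fraction = np.clip(rng.normal(0.6, 0.03, m), 0.3, 0.9)
        di = draw(scenario.diaspore_traits)
        for j in range(m):
            fruits.append(
                FruitRecord(
                    tree_id=tree_id,
                    length=float(fr["length"][j]),
                    diameter=float(fr["diameter"][j]),
                    fresh_mass=float(fr["fresh_mass"][j]),
                    pulp_yield=float(fr["fresh_mass"][j] * pulp_fraction[j]),
                )
            )
            diaspores.append(
                DiasporeRecord(
                    tree_id=tree_id,
                    length=float(di["length"][j]),
                    diameter=float(di["diameter"][j]),
                    thickness=float(di["thickness"][j]),
                    fresh_mass=float(di["fresh_mass"][j]),
                )
            )
    return fruits, diaspores


def simulate_allometry(n: int, rng: np.random.Generator) -> list[dict]:
    """Per-tree structural fields: stems, height, crown area.

    A latent log-size drives DBH; height and crown area follow noisy power
    laws of DBH; a share of trees is multi-stemmed with the squared
    circumference split among stems (so the root-sum-of-squares rule
    recovers the equivalent single stem exactly).
    """
    size = rng.standard_normal(n)
    dbh = 25.0 * np.exp(0.35 * size)
    ct = np.pi * dbh
    height = 1.7 * dbh**0.33 * np.exp(rng.normal(0, 0.15, n))
    crown = 0.35 * dbh**1.1 * np.exp(rng.normal(0, 0.30, n))
    out = []
    for i in range(n):
        n_stems = 1 + rng.binomial(3, 0.35)
        if n_stems == 1:
            stems = [float(ct[i])]
        else:
            shares = rng.dirichlet(np.full(n_stems, 2.0))
            stems = list(np.sqrt(shares) * ct[i])
        out.append(
            {
                "stem_circumferences": [float(s) for s in stems],
                "total_height": float(height[i]),
                "crown_area": float(crown[i]),
            }
        )
    return out


# ---------------------------------------------------------------------------
# full dataset

@dataclass
class SyntheticDataset:
    scenario: SimulationScenario
    trees: list[TreeRecord]
    matrix: BinaryMarkerMatrix
    fruits: list[FruitRecord]
    diaspores: list[DiasporeRecord]
    truth: dict


def simulate_dataset(scenario: SimulationScenario) -> SyntheticDataset:
    """Generate a full synthetic study: coordinates, tree structure,
    genotypes of the fruiting trees (ancestry weakly coupled to the spatial
    cluster parents), and fruit/diaspore measurements."""
    coords, parent_idx = simulate_coordinates(
        scenario, stage_rng(scenario.seed, "coordinates"), return_parents=True
    )
    rng_assign = stage_rng(scenario.seed, "assignment")
    fruiting_idx = np.sort(
        rng_assign.choice(scenario.n_trees, scenario.n_fruiting, replace=False)
    )
    allom = simulate_allometry(scenario.n_trees, stage_rng(scenario.seed, "allometry"))
    trees = []
    for i in range(scenario.n_trees):
        trees.append(
            TreeRecord(
                tree_id=f"T{i + 1:02d}",
                x=float(coords[i, 0]),
                y=float(coords[i, 1]),
                fruiting=bool(i in set(fruiting_idx)),
                **allom[i],
            )
        )

    # spatial-ancestry coupling: each parent point carries a cluster label;
    # an individual inherits it with the coupling probability
    parent_cluster = np.arange(scenario.n_parents) % max(scenario.k_true, 1)
    base = parent_cluster[parent_idx[fruiting_idx]]
    mask = rng_assign.random(scenario.n_fruiting) >= scenario.spatial_genetic_coupling
    base[mask] = rng_assign.integers(0, max(scenario.k_true, 1), mask.sum())

    ids = [trees[i].tree_id for i in fruiting_idx]
    if scenario.bottleneck is not None:
        matrix = simulate_bottleneck_population(
            scenario, stage_rng(scenario.seed, "bottleneck_population")
        )
        matrix = BinaryMarkerMatrix(
            ids, matrix.locus_ids, matrix.primer_of_locus, matrix.scores
        )
        truth = {"bottleneck": True}
    else:
        matrix, truth = simulate_genotypes(
            scenario,
            stage_rng(scenario.seed, "genotypes"),
            individual_ids=ids,
            base_cluster=None if scenario.k_true < 2 else base,
        )
        truth = dict(truth)
        truth["bottleneck"] = False
    fruits, diaspores = simulate_traits(
        scenario, matrix, stage_rng(scenario.seed, "traits")
    )
    log.info(
        "simulated dataset: %d trees (%d fruiting), %d loci, %d fruits",
        scenario.n_trees, scenario.n_fruiting, matrix.n_loci, len(fruits),
    )
    return SyntheticDataset(scenario, trees, matrix, fruits, diaspores, truth)
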