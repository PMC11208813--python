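import numpy as np
import pytest

from dompop import diversity as dv
from dompop.biometry import spearman
from dompop.synthetic import (
    BottleneckScenario,
    SimulationScenario,
    simulate_bottleneck_population,
    simulate_coordinates,
    simulate_dataset,
    simulate_genotypes,
    simulate_traits,
)
from dompop.types import stage_rng


def test_reproducible_bit_for_bit():
    a = simulate_dataset(SimulationScenario(seed=5))
    b = simulate_dataset(SimulationScenario(seed=5))
    assert (a.matrix.scores == b.matrix.scores).all()
    assert [(t.x, t.y) for t in a.trees] == [(t.x, t.y) for t in b.trees]
    assert [f.fresh_mass for f in a.fruits] == [f.fresh_mass for f in b.fruits]


def test_scenario_validation():
    with pytest.raises(ValueError, match="n_fruiting"):
        SimulationScenario(n_trees=10, n_fruiting=11)
    with pytest.raises(ValueError, match="parents"):
        SimulationScenario(n_parents=60)
    with pytest.raises(ValueError, match="drift"):
        SimulationScenario(drift=1.5)
    with pytest.raises(ValueError, match="partition"):
        SimulationScenario(n_loci=100)
    with pytest.raises(ValueError, match="N_after"):
        BottleneckScenario(n_before=100, n_after=100, generations_after=5)


def test_coordinates_degenerate_limit_parents_equal_trees():
    scenario = SimulationScenario(
        n_trees=10, n_fruiting=5, n_parents=10, dispersal_sd=1e-9,
        n_loci=10, primer_partition=(10,),
    )
    pts = simulate_coordinates(scenario, np.random.default_rng(0))
    # with sd -> 0 every point sits on a parent: pairwise snapping
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    assert ((d < 1e-6) | (d > 1.0)).all()


def test_coordinates_stay_in_window():
    scenario = SimulationScenario(seed=2)
    pts = simulate_coordinates(scenario, np.random.default_rng(2))
    xmin, xmax, ymin, ymax = scenario.window
    assert len(pts) == 53
    assert (pts[:, 0] >= xmin).all() and (pts[:, 0] <= xmax).all()
    assert (pts[:, 1] >= ymin).all() and (pts[:, 1] <= ymax).all()


def test_genotypes_hwe_within_cluster():
    """For hard single-cluster ancestry the band frequency converges to
    1 - (1 - p)^2 (HWE with dominance)."""
    scenario = SimulationScenario(
        n_trees=2000, n_fruiting=2000, n_loci=20, primer_partition=(20,),
        k_true=1, n_parents=5,
    )
    m, truth = simulate_genotypes(scenario, np.random.default_rng(3))
    p = truth["cluster_freqs"][0]
    expected = 1 - (1 - p) ** 2
    observed = m.scores.mean(axis=0)
    np.testing.assert_allclose(observed, expected, atol=0.03)


def test_default_scenario_highly_polymorphic():
    """Generator calibration: the default 23 x 103 scenario is nearly fully
    polymorphic (>= 95%) in at least 9 of 10 seeds."""
    hits = 0
    for seed in range(10):
        m, _ = simulate_genotypes(SimulationScenario(seed=seed),
                                  stage_rng(seed, "genotypes"))
        hits += dv.percent_polymorphic(m) >= 95.0
    assert hits >= 9


def test_dataset_counts_and_fruiting(default_dataset):
    assert len(default_dataset.trees) == 53
    assert sum(t.fruiting for t in default_dataset.trees) == 23
    assert default_dataset.matrix.n_individuals == 23
    assert default_dataset.matrix.n_loci == 103
    fruiting_ids = {t.tree_id for t in default_dataset.trees if t.fruiting}
    assert set(default_dataset.matrix.individual_ids) == fruiting_ids


def test_traits_positive_and_counts_in_range(default_dataset):
    masses = [f.fresh_mass for f in default_dataset.fruits]
    assert min(masses) > 0
    per_tree = {}
    for f in default_dataset.fruits:
        per_tree[f.tree_id] = per_tree.get(f.tree_id, 0) + 1
    assert all(1 <= c <= 37 for c in per_tree.values())
    assert set(per_tree) == set(default_dataset.matrix.individual_ids)


def test_fruit_trait_correlation_sign(default_dataset):
    """Fresh mass and length share tree and fruit latents: rank correlation
    across fruits is strongly positive."""
    rs, _ = spearman(
        [f.fresh_mass for f in default_dataset.fruits],
        [f.length for f in default_dataset.fruits],
    )
    assert rs > 0.5


def test_zero_genetic_weight_decouples_traits_from_genotype():
    scenario = SimulationScenario(seed=4, genetic_weight=0.0)
    m, _ = simulate_genotypes(scenario, stage_rng(4, "genotypes"))
    fruits1, _ = simulate_traits(scenario, m, np.random.default_rng(1))
    # same trait stream, permuted genotypes: identical output when w=0
    perm = np.random.default_rng(2).permutation(m.n_individuals)
    from dompop.types import BinaryMarkerMatrix

    m2 = BinaryMarkerMatrix(
        m.individual_ids, m.locus_ids, m.primer_of_locus, m.scores[perm]
    )
    fruits2, _ = simulate_traits(scenario, m2, np.random.default_rng(1))
    assert [f.fresh_mass for f in fruits1] == [f.fresh_mass for f in fruits2]


def test_bottleneck_population_polymorphic_and_shapes():
    m = simulate_bottleneck_population(
        SimulationScenario(seed=6, bottleneck=BottleneckScenario()),
        np.random.default_rng(6),
    )
    assert m.scores.shape == (23, 103)
    f = m.band_frequencies()
    assert ((f > 0) & (f < 1)).all()
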