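"""Individual clustering and matrix correlations.

UPGMA on 1 - Nei identity with a similarity cut at 0.58, cophenetic
correlation, and Mantel tests of Nei genetic distance against geographic
distance (isolation by distance) and fruit-trait Euclidean distance.
"""
from pathlib import Path

import numpy as np

from dompop import biometry as bm, genetic_structure as gs, io
from dompop.types import stage_rng

SEED = 1
BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    matrix = io.read_marker_matrix(BASE / "data" / "markers.csv")
    trees = {t.tree_id: t for t in io.read_tree_table(BASE / "data" / "trees.csv")}

    dmat = gs.genetic_distance_matrix(matrix, method="one_minus")
    tree = gs.upgma(dmat)
    (BASE / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    groups = tree.cut(1.0 - 0.58)
    coph = gs.cophenetic_correlation(tree, dmat)

    gen = gs.genetic_distance_matrix(matrix, method="neg_log")
    xy = [(trees[i].x, trees[i].y) for i in matrix.individual_ids]
    geo = gs.geographic_distance_matrix(matrix.individual_ids, xy)
    mantel_geo = gs.mantel_test(geo, gen, 999, stage_rng(SEED, "mantel_geo"))

    means = bm.per_tree_means(
        bm.fruit_frame(io.read_fruit_table(BASE / "data" / "fruits.csv")))
    traits = bm.trait_euclidean(means)
    idx = [gen.labels.index(l) for l in traits.labels]
    sub = gs.DistanceMatrix(traits.labels, gen.values[np.ix_(idx, idx)],
                            gen.metric_name)
    mantel_tr = gs.mantel_test(traits, sub, 999, stage_rng(SEED, "mantel_traits"))

    io.write_results(
        {
            "cophenetic_correlation": coph,
            "groups_at_0.58": groups,
            "mantel_geographic": mantel_geo.to_dict(),
            "mantel_traits": mantel_tr.to_dict(),
        },
        BASE / "clustering_mantel.json",
    )
    print(f"cophenetic r = {coph:.2f}; "
          f"{len(set(groups.values()))} groups at identity 0.58")
    print(f"Mantel geo:    r = {mantel_geo.r:.3f}, p = {mantel_geo.p_value:.3f}")
    print(f"Mantel traits: r = {mantel_tr.r:.3f}, p = {mantel_tr.p_value:.3f}")


if __name__ == "__main__":
    main()
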