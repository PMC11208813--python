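"""Orchestration: run every analysis stage on one dataset and emit a single
structured report (spatial pattern, allometry, fruit/diaspore biometry,
diversity, dendrogram and groups, Mantel tests, admixture/DeltaK,
bottleneck tests).

Stages are independent: each draws its randomness from a stream derived
from (root seed, stage name), so skipping one stage never changes
another's numbers, and partial inputs yield partial reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import __version__
from . import biometry as bm
from . import bottleneck as bn
from . import diversity as dv
from . import genetic_structure as gs
from . import spatial as sp
from . import admixture as ax
from .types import AnalysisConfig, BinaryMarkerMatrix, TreeRecord, stage_rng

log = logging.getLogger("dompop")

REPORT_SCHEMA_VERSION = 1


@dataclass
class StudyInputs:
    matrix: BinaryMarkerMatrix | None = None
    trees: list[TreeRecord] | None = None
    fruits: list | None = None
    diaspores: list | None = None


def _skipped(reason: str) -> dict:
    return {"skipped": reason}


def run_pipeline(config: AnalysisConfig, inputs: StudyInputs) -> dict:
    """Run all stages whose inputs exist; deterministic given the seed."""
    if inputs.matrix is None and inputs.trees is None:
        raise ValueError("need at least a marker matrix or a tree table")
    if inputs.matrix is not None and inputs.trees is not None:
        tree_ids = {t.tree_id for t in inputs.trees}
        orphans = [i for i in inputs.matrix.individual_ids if i not in tree_ids]
        if orphans:
            raise ValueError(f"genotyped individuals missing from tree table: {orphans}")

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "rng_seed": config.rng_seed,
            "config": config.to_dict(),
        },
    }
    seed = config.rng_seed

    # --- spatial ----------------------------------------------------------
    if inputs.trees is not None:
        coords = np.array([(t.x, t.y) for t in inputs.trees])
        pattern = sp.analyze_spatial(
            coords,
            class_bounds=config.distance_classes,
            n_sims=config.n_csr_sims,
            alpha=config.envelope_alpha,
            rng=stage_rng(seed, "spatial"),
        )
        report["spatial"] = pattern.to_dict()
        report["allometry"] = bm.allometry(inputs.trees).to_dict()
    else:
        report["spatial"] = _skipped("missing tree table")
        report["allometry"] = _skipped("missing tree table")

    # --- biometry ---------------------------------------------------------
    if inputs.fruits:
        frame = bm.fruit_frame(inputs.fruits)
        rng = stage_rng(seed, "biometry_fruits")
        report["fruit_biometry"] = {
            "descriptive": {
                c: bm.descriptive_stats(frame[c].dropna().to_numpy(), rng=rng).to_dict()
                for c in ("length", "diameter", "fresh_mass")
            },
            "correlations": bm.trait_correlations(frame),
        }
    else:
        report["fruit_biometry"] = _skipped("missing fruit table")
    if inputs.diaspores:
        frame = bm.diaspore_frame(inputs.diaspores)
        rng = stage_rng(seed, "biometry_diaspores")
        report["diaspore_biometry"] = {
            "descriptive": {
                c: bm.descriptive_stats(frame[c].to_numpy(), rng=rng).to_dict()
                for c in ("length", "diameter", "thickness", "fresh_mass")
            },
            "correlations": bm.trait_correlations(frame),
        }
    else:
        report["diaspore_biometry"] = _skipped("missing diaspore table")

    # --- genetics ---------------------------------------------------------
    if inputs.matrix is not None:
        matrix = inputs.matrix
        report["diversity"] = dv.summarize(matrix).to_dict()

        dmat = gs.genetic_distance_matrix(matrix, method="one_minus")
        tree = gs.upgma(dmat)
        cut_height = 1.0 - config.dendrogram_cut
        report["clustering"] = {
            "newick": tree.to_newick(),
            "cophenetic_correlation": gs.cophenetic_correlation(tree, dmat),
            "cut_identity": config.dendrogram_cut,
            "groups": tree.cut(cut_height),
        }

        gen_dist = gs.genetic_distance_matrix(matrix, method="neg_log")
        if inputs.trees is not None:
            by_id = {t.tree_id: t for t in inputs.trees}
            xy = [(by_id[i].x, by_id[i].y) for i in matrix.individual_ids]
            geo = gs.geographic_distance_matrix(matrix.individual_ids, xy)
            report["mantel_geographic"] = gs.mantel_test(
                geo, gen_dist, config.mantel_permutations,
                stage_rng(seed, "mantel_geo"),
            ).to_dict()
        else:
            report["mantel_geographic"] = _skipped("missing tree table")
        if inputs.fruits:
            means = bm.per_tree_means(bm.fruit_frame(inputs.fruits))
            means = means.loc[[i for i in matrix.individual_ids if i in means.index]]
            try:
                traits = bm.trait_euclidean(means)
                shared = [l for l in gen_dist.labels if l in traits.labels]
                idx = [gen_dist.labels.index(l) for l in shared]
                sub = gs.DistanceMatrix(
                    shared, gen_dist.values[np.ix_(idx, idx)], gen_dist.metric_name
                )
                report["mantel_traits"] = gs.mantel_test(
                    traits, sub, config.mantel_permutations,
                    stage_rng(seed, "mantel_traits"),
                ).to_dict()
            except ValueError as exc:
                report["mantel_traits"] = _skipped(str(exc))
        else:
            report["mantel_traits"] = _skipped("missing fruit table")

        runs = ax.run_k_range(
            matrix,
            k_min=config.mcmc.k_min,
            k_max=config.mcmc.k_max,
            n_runs=config.mcmc.n_runs,
            burn_in=config.mcmc.burn_in,
            iterations=config.mcmc.iterations,
            seed=seed,
        )
        table = ax.evanno(runs)
        report["admixture"] = table.to_dict()

        report["bottleneck"] = {}
        for model in config.bottleneck.models:
            result = bn.bottleneck_test(
                matrix, model,
                n_sims=config.bottleneck.n_coalescent_sims,
                rng=stage_rng(seed, f"bottleneck_{model}"),
            )
            d = result.to_dict()
            d.pop("he_observed")  # keep the report compact
            report["bottleneck"][model] = d
    else:
        for key in ("diversity", "clustering", "mantel_geographic",
                    "mantel_traits", "admixture", "bottleneck"):
            report[key] = _skipped("missing marker matrix")
    return report
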