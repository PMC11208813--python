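"""Generate the default synthetic study population.

Writes the marker matrix, tree table and fruit/diaspore tables for a
53-tree population (23 fruiting trees genotyped at 103 dominant loci in
10 primer groups) to results/data/, plus the generator's ground truth.
"""
from pathlib import Path

from dompop import io
from dompop.synthetic import SimulationScenario, simulate_dataset

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(SimulationScenario(seed=SEED))
    io.write_marker_matrix(data.matrix, OUT / "markers.csv")
    io.write_tree_table(data.trees, OUT / "trees.csv")
    io.write_fruit_table(data.fruits, OUT / "fruits.csv")
    io.write_diaspore_table(data.diaspores, OUT / "diaspores.csv")
    io.write_results(
        {
            "Q_true": data.truth.get("Q_true"),
            "bottleneck": data.truth["bottleneck"],
            "scenario": data.scenario.to_dict(),
        },
        OUT / "truth.json",
    )
    print(f"simulated {len(data.trees)} trees "
          f"({sum(t.fruiting for t in data.trees)} fruiting/genotyped), "
          f"{data.matrix.n_loci} loci, {len(data.fruits)} fruits -> {OUT}")


if __name__ == "__main__":
    main()
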