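"""Fruit/diaspore biometry and allometry.

Writes descriptive statistics (mean, SE, CV%, G1, G2, Lilliefors p),
trait rank correlations, and the DBH/height/crown Spearman table.
"""
from pathlib import Path

from dompop import biometry as bm, io
from dompop.types import stage_rng

SEED = 1
BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    fruits = bm.fruit_frame(io.read_fruit_table(BASE / "data" / "fruits.csv"))
    diaspores = bm.diaspore_frame(
        io.read_diaspore_table(BASE / "data" / "diaspores.csv"))
    trees = io.read_tree_table(BASE / "data" / "trees.csv")
    rng = stage_rng(SEED, "biometry")
    report = {
        "fruits": {
            "descriptive": {
                c: bm.descriptive_stats(fruits[c].to_numpy(), rng=rng).to_dict()
                for c in ("length", "diameter", "fresh_mass")
            },
            "correlations": bm.trait_correlations(fruits),
        },
        "diaspores": {
            "descriptive": {
                c: bm.descriptive_stats(diaspores[c].to_numpy(), rng=rng).to_dict()
                for c in ("length", "diameter", "thickness", "fresh_mass")
            },
            "correlations": bm.trait_correlations(diaspores),
        },
        "allometry": bm.allometry(trees).to_dict(),
    }
    io.write_results(report, BASE / "biometry.json")
    fm = report["fruits"]["descriptive"]["fresh_mass"]
    print(f"fruit fresh mass: mean {fm['mean']:.2f} g, CV {fm['cv_percent']:.1f}%")
    for name, c in report["allometry"]["correlations"].items():
        print(f"  {name}: rs = {c['rs']:.2f} (p = {c['p']:.2g})")


if __name__ == "__main__":
    main()
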