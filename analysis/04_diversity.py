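"""Dominant-marker diversity: %P, Na, Ne, h, I and PIC per locus and primer."""
from pathlib import Path

from dompop import diversity as dv, io

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    matrix = io.read_marker_matrix(BASE / "data" / "markers.csv")
    summary = dv.summarize(matrix)
    io.write_results(summary.to_dict(), BASE / "diversity.json")
    dv.locus_table(matrix).to_csv(BASE / "diversity_loci.csv", index=False)
    print(f"%P = {summary.percent_polymorphic:.2f}; "
          f"Na = {summary.na_mean:.2f} +- {summary.na_sd:.2f}; "
          f"Ne = {summary.ne_mean:.2f}; h = {summary.h_mean:.2f}; "
          f"I = {summary.i_mean:.2f}; PIC = {summary.pic_mean:.2f}")


if __name__ == "__main__":
    main()
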