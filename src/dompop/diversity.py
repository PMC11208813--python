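"""Dominant-marker genetic diversity statistics.

Dominant markers show only band presence/absence, so allele frequencies
must be reconstructed under Hardy-Weinberg equilibrium: the null-allele
frequency is q = sqrt(1 - f) where f is the band-phenotype frequency (the
square-root estimator, the classic desktop-program convention for dominant
data).  From (p, q) the per-locus statistics follow:

* Na — observed allele count (2 if the locus varies, else 1)
* Ne = 1 / (p^2 + q^2) — effective allele number
* h  = 1 - p^2 - q^2 — Nei gene diversity (expected heterozygosity)
* I  = -(p ln p + q ln q) — Shannon information index (natural log)
* PIC = 1 - f^2 - (1-f)^2 — polymorphic information content, computed on
  the band-*phenotype* basis (which is why mean PIC and mean h differ)

A Lynch-Milligan bias-corrected estimator is exposed as an option but is
not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .types import BinaryMarkerMatrix


def band_frequency(matrix: BinaryMarkerMatrix, locus: str) -> float:
    """Fraction of individuals showing the band at one locus."""
    j = matrix.locus_ids.index(locus)
    return float(matrix.scores[:, j].mean())


def estimate_allele_frequencies(f, n: int | None = None, method: str = "sqrt"):
    """Estimate (p, q) = (presence, null) allele frequencies from band
    frequency f under HWE.

    ``method="sqrt"``: q = sqrt(1 - f) (default).
    ``method="lynch-milligan"``: bias-corrected q = sqrt(x) / (1 - Var(x)/(8 x^2))
    with x = 1 - f and Var(x) = x(1-x)/n; requires the sample size n.
    """
    f = np.asarray(f, dtype=float)
    x = 1.0 - f
    if method == "sqrt":
        q = np.sqrt(x)
    elif method == "lynch-milligan":
        if n is None:
            raise ValueError("lynch-milligan estimator needs the sample size n")
        with np.errstate(divide="ignore", invalid="ignore"):
            var = x * (1.0 - x) / n
            corr = 1.0 - var / (8.0 * x**2)
            q = np.where(x > 0, np.sqrt(np.maximum(x, 0)) / corr, 0.0)
        q = np.clip(q, 0.0, 1.0)
    else:
        raise ValueError(f"unknown estimator {method!r}")
    return 1.0 - q, q


def locus_statistics(p, q, f) -> dict[str, np.ndarray]:
    """Per-locus diversity statistics from allele and phenotype frequencies."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    f = np.asarray(f, dtype=float)
    if not np.allclose(p + q, 1.0):
        raise ValueError("p + q must equal 1")
    polymorphic = (f > 0) & (f < 1)
    na = np.where(polymorphic, 2, 1)
    homozygosity = p**2 + q**2
    ne = 1.0 / homozygosity
    h = 1.0 - homozygosity
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = -(np.where(p > 0, p * np.log(p), 0.0)
                    + np.where(q > 0, q * np.log(q), 0.0))
    pic = 1.0 - f**2 - (1.0 - f) ** 2
    return {
        "polymorphic": polymorphic,
        "na": na,
        "ne": ne,
        "h": h,
        "i": shannon,
        "pic": pic,
    }


def percent_polymorphic(matrix: BinaryMarkerMatrix) -> float:
    """Percentage of loci with any variation in the sample (0 < f < 1)."""
    f = matrix.band_frequencies()
    return float(100.0 * np.mean((f > 0) & (f < 1)))


@dataclass
class DiversitySummary:
    n_individuals: int
    n_loci: int
    per_primer_counts: dict[str, int]
    loci_per_primer_mean: float
    percent_polymorphic: float
    na_mean: float
    na_sd: float
    ne_mean: float
    ne_sd: float
    h_mean: float
    h_sd: float
    i_mean: float
    i_sd: float
    pic_mean: float
    pic_per_primer: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


def locus_table(matrix: BinaryMarkerMatrix, method: str = "sqrt") -> pd.DataFrame:
    """Full per-locus table of frequencies and diversity statistics."""
    f = matrix.band_frequencies()
    p, q = estimate_allele_frequencies(f, n=matrix.n_individuals, method=method)
    stats = locus_statistics(p, q, f)
    return pd.DataFrame(
        {
            "locus": matrix.locus_ids,
            "primer": [matrix.primer_of_locus[l] for l in matrix.locus_ids],
            "f": f,
            "p": p,
            "q": q,
            **stats,
        }
    )


def summarize(matrix: BinaryMarkerMatrix, method: str = "sqrt") -> DiversitySummary:
    """Population-level summary: %P, mean +/- sd of Na, Ne, h, I, and PIC
    (overall and per primer)."""
    table = locus_table(matrix, method=method)
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    per_primer = table.groupby("primer", sort=True)
    counts = {k: int(v) for k, v in per_primer.size().items()}
    return DiversitySummary(
        n_individuals=matrix.n_individuals,
        n_loci=matrix.n_loci,
        per_primer_counts=counts,
        loci_per_primer_mean=float(np.mean(list(counts.values()))),
        percent_polymorphic=float(100.0 * table["polymorphic"].mean()),
        na_mean=float(table["na"].mean()),
        na_sd=sd(table["na"]),
        ne_mean=float(table["ne"].mean()),
        ne_sd=sd(table["ne"]),
        h_mean=float(table["h"].mean()),
        h_sd=sd(table["h"]),
        i_mean=float(table["i"].mean()),
        i_sd=sd(table["i"]),
        pic_mean=float(table["pic"].mean()),
        pic_per_primer={k: float(v) for k, v in per_primer["pic"].mean().items()},
    )
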