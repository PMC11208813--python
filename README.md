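# dompop

Intrapopulation analysis of dominant-marker tree population data.

`dompop` re-implements, as one tested pipeline, the complete desk analysis
of a small natural tree population surveyed in the field and genotyped
with dominant multilocus markers (ISSR/RAPD band presence/absence):

* **Spatial pattern** — second-order neighbour density function (NDF,
  the O-ring statistic) per 10 m distance class, with Monte Carlo
  complete-spatial-randomness envelopes (499 simulations, α = 0.01).
* **Biometry & allometry** — descriptive statistics of fruit and diaspore
  measurements (mean, SE, CV%, skewness G1, excess kurtosis G2, Monte
  Carlo Lilliefors normality test), Spearman trait correlations, and the
  multi-stem circumference collapse `Ct = √(Σ cᵢ²)`, `DBH = Ct/π`.
* **Genetic diversity** — dominant markers hide the heterozygote, so the
  null-allele frequency is estimated under HWE as `q = √(1 − f)` from the
  band-phenotype frequency `f`; per locus the pipeline reports
  `Na`, `Ne = 1/(p² + q²)`, Nei gene diversity `h = 1 − p² − q²`, Shannon
  `I = −(p ln p + q ln q)` and `PIC = 1 − f² − (1−f)²` (phenotype basis),
  plus %P and per-primer summaries.
* **Clustering & matrix correlation** — Nei identity between individual
  band profiles, UPGMA dendrogram (Newick export, cophenetic correlation,
  similarity-threshold cut), and one-sided Mantel permutation tests of
  genetic distance against geographic and fruit-trait Euclidean distances.
* **Bayesian admixture** — a Gibbs sampler for the admixture model with
  correlated (F-model) cluster frequencies and latent-genotype treatment
  of dominance; multi-run lnP(D) aggregation and Evanno ΔK model
  selection over K = 1..4.
* **Bottleneck tests** — heterozygosity-excess tests under the infinite
  allele (IAM) and stepwise mutation (SMM) models: coalescent simulation
  of the equilibrium gene diversity conditional on the observed allele
  count, and an exact Poisson-binomial sign test.

A first-class synthetic-data generator (`dompop.synthetic`) produces
populations with known ground truth — Thomas-process coordinates, F-model
two-cluster genotypes under dominance, trait tables with a configurable
genetic component, and forward Wright–Fisher bottleneck histories — so
every stage is testable end to end.

## Worked example

```bash
python analysis/01_simulate.py      # default study population
python analysis/04_diversity.py
python analysis/06_admixture.py
```

prints (seed 1):

```
simulated 53 trees (23 fruiting/genotyped), 103 loci, 200 fruits -> results/data
%P = 99.03; Na = 1.99 +- 0.10; Ne = 1.61; h = 0.35; I = 0.52; PIC = 0.38
mean lnP(D): {1: -1398.9, 2: -1355.9, 3: -1399.3, 4: -1442.2}
modal K = 2 (DeltaK = {2: 11.3, 3: 0.0})
```

Of the 103 dominant loci, 99% are polymorphic in the 23 genotyped trees;
mean gene diversity h = 0.35 indicates moderate variation; and the Evanno
ΔK criterion recovers the two ancestral clusters the generator planted
(ΔK peaks at K = 2). The remaining drivers (`02_spatial`, `03_biometry`,
`05_clustering_mantel`, `07_bottleneck`, `08_report`) run the other
stages and write their tables under `results/`.

The same stages are available as a CLI
(`dompop simulate|diversity|cluster|spatial|mantel|structure|bottleneck|biometry|report`).

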