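# Methods

This note documents the statistical models behind `dompop`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing
its output.

## Dominant-marker estimation

A dominant locus shows a band if at least one chromosome carries the
presence allele, so only the null homozygote is identifiable. With
band-phenotype frequency `f` in a sample of `n` diploids, the pipeline
estimates the null-allele frequency under Hardy–Weinberg equilibrium as
`q = √(1 − f)` (the square-root estimator, the convention of the classic
dominant-data programs). The Lynch–Milligan bias-corrected estimator is
available via `estimate_allele_frequencies(..., method="lynch-milligan")`
but is not the default. From `(p, q)`:

* `Na = 2` if `0 < f < 1` else 1, so mean Na ≡ 1 + %P/100 identically;
* `Ne = 1/(p² + q²)`, `h = 1 − p² − q²` (≤ 0.5 for biallelic loci);
* `I = −(p ln p + q ln q)` with natural logs (maximum ln 2 ≈ 0.693 — we
  do not rescale to a 0–1 range);
* `PIC = 1 − f² − (1 − f)²` is deliberately computed on the band-
  *phenotype* frequencies, not the allele estimates; this is why mean PIC
  and mean h differ on the same data.
* A locus is called polymorphic whenever `0 < f < 1`; no 95% criterion.

## Clustering and Mantel tests

Nei's normalized identity is specialized to individual 0/1 profiles as
`I_xy = Σxy/√(Σx²·Σy²)` (cosine similarity of band vectors); all-zero
profiles get identity 0 with a warning. The UPGMA dendrogram is built on
`d = 1 − identity`, with size-weighted average linkage and merge height
equal to the merging distance itself, so a similarity cut at 0.58 is the
height cut `1 − 0.58 = 0.42`. Ties are broken by the lexicographically
smallest representative-label pair, making output invariant to input row
order. For the isolation-by-distance test the genetic matrix uses Nei's
distance `−ln(identity)`, capped at `−ln(1/(2L))` when identity is 0.

The Mantel statistic is the Pearson correlation of the n(n−1)/2
off-diagonal pairs; the null permutes rows and columns of the second
matrix simultaneously, and the p-value is one-sided (greater),
`p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm)`, with 1000 permutations by
default. Trait Euclidean distances are computed on z-standardized
tree-level trait means by default, because traits mix units (mm, g).

## Spatial statistics

The NDF for class `(t_{k−1}, t_k]` is the mean neighbour count per unit
annulus area, with no edge correction: the statistic stays exactly
auditable, and the CSR envelope is built from the *same* uncorrected
statistic on uniform points in the same window, so the Monte Carlo test
is valid by construction. The envelope is a pointwise rank envelope: with
`n_sims = 499` and `α = 0.01`, the 3rd smallest and 3rd largest simulated
values per class (`k = ⌈α/2·(n_sims+1)⌉`). The default window is the
axis-aligned bounding box of the observed points padded by 1 m; distance
classes default to 10 m steps up to 100 m.

## Admixture model

Each individual's two allele copies at each locus originate from one of
K clusters with individual proportions `Q_i ~ Dirichlet(α·1)`, α fixed at
1 by default. Cluster presence-allele frequencies follow the correlated-
frequency F-model: `P_kl ~ Beta(p_l(1−F)/F, (1−p_l)(1−F)/F)` with a
shared drift parameter F (default 0.05) and per-locus ancestral
frequencies `p_l` given a uniform prior, updated with a reflected
random-walk Metropolis step. Dominance is handled by latent-genotype
augmentation: band absent forces both copies null; band present draws
the copy pair from (presence,presence), (presence,null), (null,presence)
with probabilities ∝ (s², su, us), where s and u are the copy-level
presence/null mixture weights. Everything else is conjugate Gibbs.

Model evidence per run is `lnP(D) = mean(lnL) − var(lnL)/2` over
post-burn-in sweeps; the number of clusters is chosen by Evanno's
`ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K))` across independent runs,
defined for interior K only; if no ΔK is defined the lowest K is
reported. Label switching across runs is resolved by Hungarian
assignment on the Q-overlap matrix. MCMC defaults are scaled down
(burn-in 5 000, 10 000 iterations, 5 runs, K 1–4) relative to the
500k/250k settings of the original desktop program; the analysis scripts
and acceptance checks use burn-in 300–1 000 and 600–2 000 iterations,
which the recovery tests show are sufficient at these data sizes
(n ≤ 46, L ≤ 103).

## Bottleneck tests

A recently bottlenecked population loses rare alleles faster than
heterozygosity, so observed gene diversity He exceeds the equilibrium
expectation Heq given the observed allele count. All dominant-derived
loci are biallelic, so Heq is always simulated conditional on k = 2
alleles: a Kingman coalescent genealogy of the 2n sampled gene copies,
Poisson mutations on branches with θ chosen by bisection so the expected
allele count equals 2 (Ewens' formula for IAM, seeded simulation for
SMM), and rejection on exactly 2 observed alleles. Under IAM a mutated
branch ends in a fresh allele; under SMM the state takes a ±1 random
walk.

Two constructions matter for dominant data and are deliberate:

1. **Observability conditioning.** A dominant locus is only ever scored
   when its band phenotype varies in the sample; and He is not observed
   directly but reconstructed through the square-root estimator. The
   simulated null therefore pairs the sampled gene copies into
   individuals, applies dominance with a randomly labelled presence
   allele, rejects phenotype-monomorphic samples, and computes Heq
   through the same estimator. Without this the test rejects on
   equilibrium data essentially always; with it the type-I error is at
   the nominal 5% level (verified over seeded replicates).
2. **Sign-test null.** The per-locus excess probability under
   equilibrium is `P_l = P(Heq draw > mean Heq)`, estimated from the
   simulated sample (the Cornuet–Luikart construction — this is what
   makes the expected excess count differ from L/2). The observed count
   of loci with `He > mean Heq` is tested against the exact
   Poisson-binomial distribution (O(L²) dynamic programming), two-sided
   by tail doubling.

Note the direction at fixed k: the stepwise model retains *more*
heterozygosity per observed allele than the infinite-allele model
(simulated means ≈ 0.25 vs 0.23 at 2n = 46), which is why loci evolving
under SMM can show spurious deficiency when judged against an IAM null.

## Biometry conventions

CV = 100·sd/mean with the n−1 sample sd; G1 is the adjusted
Fisher–Pearson sample skewness and G2 the bias-corrected excess kurtosis
(scipy `bias=False`). The Lilliefors normality p-value is Monte Carlo:
the KS distance of the standardized sample to N(0,1) compared with
≥ 10⁴ seeded normal samples with mean and sd re-estimated each time.
Multi-stem trees collapse to `Ct = √(Σ cᵢ²)` (preserves basal area; plain
summation available behind `rule="sum"` for sensitivity analysis), then
`DBH = Ct/π`.

## Synthetic-data generator

The generator's defaults emulate the structure of a small semi-arid
fruit-tree population: 53 trees from a Thomas cluster process (5 parents,
5 m dispersal sd, 100 m × 100 m window), 23 fruiting trees genotyped at
103 loci in 10 primer groups (7,10,10,9,11,12,12,11,12,9), two ancestral
clusters under the F-model (drift 0.2, ancestral presence-allele
frequencies U(0.1, 0.5)), weak spatial-ancestry coupling (an individual
inherits its spatial parent's cluster with probability 0.6 — the
isolation-by-distance knob, our choice since no effect size is published
for it), and fruit/diaspore traits with the observed mean/CV structure
(fruit length 31.12 mm/10%, diameter 28.68 mm/12%, fresh mass
15.56 g/30%; diaspore length 19.27 mm, diameter 13.95 mm, thickness
11.14 mm, fresh mass 2.28 g). Loci whose band would be absent in every
sampled individual are redrawn: such columns are unobservable on a gel,
which is also what makes the default scenario ~99% polymorphic.

Traits follow a variance-components model: a per-tree latent
`u = w·g + √(1−w²)·η` (g = standardized band count, w = genetic weight,
default 0.35), a per-fruit shared size latent, and independent
measurement noise, with loadings (0.5, 0.6, √(1−0.61)); each measurement
is `mean·(1 + CV·z)` with non-positive draws resampled. This gives the
strong positive within-fruit trait correlations seen in real fruit
biometry while keeping the trait–genotype coupling a single knob
(w = 0 decouples traits from the genotype exactly). Fruit counts per
tree are 1 + negative-binomial (mean ≈ 9, clipped at 37). Allometry uses
a latent log-size driving DBH, with height and crown area as noisy power
laws; multi-stem trees split the squared circumference so the
root-sum-of-squares rule recovers the equivalent stem exactly.

Bottleneck histories are forward Wright–Fisher per biallelic locus:
stationary Beta(θ, θ) initialization, 2N burn-in generations at
N_before = 500, then an instantaneous collapse to N_after = 10 for
5 generations (severe scenario); individuals are sampled by
infinite-gamete draws from the final frequency. The default mutation
rate 2×10⁻⁵ (θ = 0.04) keeps loci in the single-origin regime the
k-conditioned coalescent null assumes.

What the generator does **not** emulate: spatially explicit gene flow
beyond the parent-cluster coupling, selection, pedigree structure,
linkage between loci, genotyping/scoring error, and any correlation
between demographic history and the two-cluster structure (bottleneck
scenarios are panmictic). Passing tests therefore demonstrate estimator
and test correctness under the stated models, not robustness to scoring
artefacts or more complex demography.

## Numerical conventions

* One root seed; every stochastic stage derives an independent stream
  from (seed, stage name) via SHA-256, so stages are reproducible in
  isolation and skipping one never changes another.
* Beta draws and frequency mixtures are clipped to [1e-9, 1−1e-9] inside
  the Gibbs sampler to keep the likelihood finite.
* θ bisection runs in log space (30 steps IAM, 10 steps SMM with 400
  simulations per evaluation and a fixed internal seed, cached per
  (n_genes, model)).
* Missing genotype data are rejected, not imputed.
* Problem sizes in tests and the acceptance script (n ≤ 46, L ≤ 103,
  600–2 000 MCMC sweeps, 499 CSR simulations, 600–800 coalescent
  acceptances) were chosen so every check completes in seconds to a few
  minutes while leaving the statistical assertions well-powered.

## Known limitations

* The square-root estimator is biased at small n; the bottleneck null
  absorbs this by construction, but the diversity summaries inherit it.
* The uncorrected NDF underestimates neighbour density near window
  borders; since the envelope shares the bias the *test* is valid, but
  NDF values should not be compared across windows of different shape.
* ΔK cannot select K = 1 (it is defined for interior K only); the
  no-structure case is better judged from lnP(D) directly, as the
  negative-control test does.
* The admixture sampler fixes α and shares one drift parameter across
  clusters; both are adequate at these data sizes but are simplifications.
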