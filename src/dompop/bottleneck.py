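"""Heterozygosity-excess bottleneck tests (IAM / SMM) for dominant data.

At mutation-drift equilibrium, the gene diversity expected from the number
of alleles observed in a sample (Heq) can be simulated with the coalescent;
a recently bottlenecked population loses rare alleles faster than it loses
heterozygosity, so its observed gene diversity He sits above Heq at more
loci than expected.  Here every locus is biallelic (dominant markers), so
Heq is always simulated conditional on exactly two alleles; allele
frequencies enter from the square-root HWE estimates of the diversity
module.

The sign test compares the observed count of excess loci with its
Poisson-binomial null built from the per-locus excess probabilities under
equilibrium (computed from the simulated Heq sample), evaluated exactly by
dynamic programming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .types import BinaryMarkerMatrix
from .diversity import estimate_allele_frequencies

log = logging.getLogger("dompop")

MODELS = ("IAM", "SMM")

_THETA_CACHE: dict[tuple, float] = {}


def observed_he(p: float, n_individuals: int) -> float:
    """Unbiased gene diversity He = (2n/(2n-1)) (1 - p^2 - q^2)."""
    q = 1.0 - p
    two_n = 2 * n_individuals
    return two_n / (two_n - 1) * (1.0 - p**2 - q**2)


# ---------------------------------------------------------------------------
# coalescent machinery

def _coalescent_tree(n_genes: int, rng: np.random.Generator):
    """Kingman coalescent genealogy of ``n_genes`` sampled gene copies.

    Returns (parent, branch_length) arrays over 2n-1 nodes (leaves first,
    root parent = -1); time in coalescent units of 2N generations.
    """
    total = 2 * n_genes - 1
    parent = np.full(total, -1, dtype=int)
    node_time = np.zeros(total)
    active = list(range(n_genes))
    t = 0.0
    nxt = n_genes
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = active[i1], active[i2]
        for idx in sorted((i1, i2), reverse=True):
            active.pop(idx)
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        active.append(nxt)
        nxt += 1
    lengths = np.zeros(total)
    has_parent = parent >= 0
    lengths[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    return parent, lengths


def _mutate_states(parent, lengths, theta, model, rng) -> np.ndarray:
    """Allelic states at the leaves given mutations Poisson(theta/2 * length)
    per branch.  IAM: any mutated branch ends in a brand-new allele; SMM:
    the state takes a +/-1 random walk of the branch's mutation count."""
    total = len(parent)
    n_genes = (total + 1) // 2
    muts = rng.poisson(theta / 2.0 * lengths)
    children: dict[int, list[int]] = {}
    for node, par in enumerate(parent):
        if par >= 0:
            children.setdefault(par, []).append(node)
    states = np.zeros(total, dtype=int)
    next_allele = 1
    # iterate nodes root-down (parents always have higher index than children)
    for node in range(total - 1, -1, -1):
        par = parent[node]
        if par < 0:
            continue
        m = muts[node]
        if m == 0:
            states[node] = states[par]
        elif model == "IAM":
            states[node] = next_allele
            next_allele += 1
        else:  # SMM
            steps = rng.choice((-1, 1), size=m).sum()
            states[node] = states[par] + steps
    return states[:n_genes]


def _simulate_k_and_he(n_genes, theta, model, rng):
    parent, lengths = _coalescent_tree(n_genes, rng)
    states = _mutate_states(parent, lengths, theta, model, rng)
    _, counts = np.unique(states, return_counts=True)
    freqs = counts / n_genes
    he = n_genes / (n_genes - 1) * (1.0 - (freqs**2).sum())
    return len(counts), he


def _expected_k_iam(theta: float, n_genes: int) -> float:
    """Ewens: E[K] = sum_{i=0}^{n-1} theta / (theta + i)."""
    i = np.arange(n_genes)
    return float((theta / (theta + i)).sum())


def choose_theta(
    n_genes: int,
    model: str,
    target_k: float = 2.0,
    rng: np.random.Generator | None = None,
    n_sims_per_eval: int = 400,
) -> float:
    """Bisection for the theta whose expected allele count equals target_k.

    IAM uses the Ewens closed form; SMM estimates E[K] by simulation at each
    bisection point.  With no rng given, a fixed internal seed is used so
    theta is a deterministic function of (n_genes, model): the calibration
    is a numerical procedure, not a source of statistical noise.
    """
    deterministic = rng is None
    cache_key = (n_genes, model, target_k, n_sims_per_eval)
    if deterministic and cache_key in _THETA_CACHE:
        return _THETA_CACHE[cache_key]
    lo, hi = 1e-4, 50.0
    if model == "IAM":
        f = lambda th: _expected_k_iam(th, n_genes) - target_k
    elif model == "SMM":
        rng = rng or np.random.default_rng(1_048_576 + n_genes)

        def f(th):
            ks = [
                _simulate_k_and_he(n_genes, th, "SMM", rng)[0]
                for _ in range(n_sims_per_eval)
            ]
            return float(np.mean(ks)) - target_k
    else:
        raise ValueError(f"unknown mutation model {model!r}")
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise RuntimeError("theta bracket does not contain the target allele count")
    for _ in range(30 if model == "IAM" else 10):
        mid = np.sqrt(lo * hi)  # bisect in log space
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    theta = float(np.sqrt(lo * hi))
    if deterministic:
        _THETA_CACHE[cache_key] = theta
    return theta


def simulate_heq(
    n_genes: int,
    model: str,
    n_sims: int = 1_000,
    rng: np.random.Generator | None = None,
    k_alleles: int = 2,
    theta: float | None = None,
    dominant: bool = False,
) -> np.ndarray:
    """Sample of equilibrium gene diversities conditional on ``k_alleles``
    observed alleles (rejection sampling of coalescent simulations).

    With ``dominant=True`` the null matches how dominant loci are actually
    observed and measured: the sampled gene copies are paired into
    individuals, one allele is randomly labelled the band-presence allele,
    samples whose band phenotype is monomorphic are rejected (such loci
    are never scored), and Heq is computed through the same square-root
    HWE estimator applied to real data.  Without it, Heq is the unbiased
    gene diversity of the sampled allele frequencies directly.
    """
    if n_genes < 4:
        raise ValueError("need at least 4 gene copies")
    if dominant and n_genes % 2:
        raise ValueError("dominant mode needs an even number of gene copies")
    rng = rng or np.random.default_rng()
    if theta is None:
        theta = choose_theta(n_genes, model, target_k=k_alleles)
    n_ind = n_genes // 2
    out = np.empty(n_sims)
    accepted = 0
    attempts = 0
    max_attempts = max(1000, int(n_sims / 1e-3))
    while accepted < n_sims:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "rejection acceptance rate below 1e-3; revise the theta grid"
            )
        parent, lengths = _coalescent_tree(n_genes, rng)
        states = _mutate_states(parent, lengths, theta, model, rng)
        alleles, counts = np.unique(states, return_counts=True)
        if len(alleles) != k_alleles:
            continue
        if dominant:
            presence = alleles[rng.integers(len(alleles))]
            is_presence = states == presence
            # coalescent leaves are exchangeable: pair consecutive copies
            bands = is_presence.reshape(n_ind, 2).any(axis=1)
            f = bands.mean()
            if f == 0 or f == 1:
                continue  # unobservable / unscoreable locus
            p_hat = 1.0 - np.sqrt(1.0 - f)
            out[accepted] = observed_he(float(p_hat), n_ind)
        else:
            freqs = counts / n_genes
            out[accepted] = n_genes / (n_genes - 1) * (1.0 - (freqs**2).sum())
        accepted += 1
    return out


# ---------------------------------------------------------------------------
# sign test

def poisson_binomial_pmf(probs) -> np.ndarray:
    """Exact PMF of a sum of independent Bernoulli(p_l) by dynamic
    programming; O(L^2)."""
    probs = np.asarray(probs, dtype=float)
    pmf = np.zeros(len(probs) + 1)
    pmf[0] = 1.0
    for p in probs:
        pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
        pmf[0] *= 1 - p
    return pmf


def sign_test(excess_flags, excess_probs) -> tuple[float, float]:
    """(n_expected, two-sided p) for the observed count of excess loci.

    n_expected = sum of per-locus equilibrium excess probabilities; the
    p-value doubles the smaller tail of the exact Poisson-binomial
    distribution (capped at 1).
    """
    flags = np.asarray(excess_flags, dtype=bool)
    probs = np.asarray(excess_probs, dtype=float)
    if len(flags) != len(probs) or len(flags) == 0:
        raise ValueError("need matching, non-empty flags and probabilities")
    observed = int(flags.sum())
    pmf = poisson_binomial_pmf(probs)
    lower = float(pmf[: observed + 1].sum())
    upper = float(pmf[observed:].sum())
    p = min(1.0, 2 * min(lower, upper))
    return float(probs.sum()), p


@dataclass
class BottleneckResult:
    model: str
    n_loci_used: int
    he_observed: list[float]
    heq_mean: float
    n_excess_observed: int
    n_excess_expected: float
    p_value: float

    def to_dict(self) -> dict:
        return asdict(self)


def bottleneck_test(
    matrix: BinaryMarkerMatrix,
    model: str,
    n_sims: int = 1_000,
    rng: np.random.Generator | None = None,
    estimator: str = "sqrt",
) -> BottleneckResult:
    """Full heterozygosity-excess test for one mutation model.

    Monomorphic loci are excluded.  All loci share k = 2 alleles and the
    same sample size, so one simulated Heq sample serves every locus.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    rng = rng or np.random.default_rng()
    f = matrix.band_frequencies()
    poly = (f > 0) & (f < 1)
    if not poly.any():
        raise ValueError("no polymorphic loci")
    p, _ = estimate_allele_frequencies(f[poly], n=matrix.n_individuals,
                                       method=estimator)
    n = matrix.n_individuals
    he_obs = np.array([observed_he(pi, n) for pi in p])
    heq = simulate_heq(2 * n, model, n_sims=n_sims, rng=rng, k_alleles=2,
                       dominant=True)
    heq_mean = float(heq.mean())
    flags = he_obs > heq_mean
    # equilibrium probability that a locus shows excess, from the same sample
    p_excess = float((heq > heq_mean).mean())
    probs = np.full(flags.sum() + (~flags).sum(), p_excess)
    n_expected, p_value = sign_test(flags, probs)
    log.info(
        "%s bottleneck test: %d/%d excess loci (expected %.1f), p=%.4g",
        model, int(flags.sum()), len(flags), n_expected, p_value,
    )
    return BottleneckResult(
        model=model,
        n_loci_used=int(poly.sum()),
        he_observed=[float(v) for v in he_obs],
        heq_mean=heq_mean,
        n_excess_observed=int(flags.sum()),
        n_excess_expected=n_expected,
        p_value=p_value,
    )
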