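"""Bayesian admixture clustering for dominant binary markers.

Model: each individual's two allele copies at a locus originate from the K
clusters with individual-specific proportions Q (Dirichlet prior with
concentration alpha); cluster presence-allele frequencies P follow a
correlated-frequency (F-model) prior, Beta centred on an ancestral
frequency with variance set by a drift parameter.  Dominance is handled by
latent-genotype augmentation: band absent forces both copies null, band
present marginalizes over the genotypes with at least one presence copy.

Inference is a Gibbs sampler over (latent genotypes and origins, P, Q,
ancestral frequencies).  Model evidence is estimated as
lnP(D) = mean(lnL) - var(lnL)/2 over post-burn-in samples, and the number
of clusters is selected with the Evanno second-order rate of change,
DeltaK = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import betaln

from .types import BinaryMarkerMatrix, stage_rng

_EPS = 1e-9


@dataclass
class StructureRun:
    K: int
    seed: int
    Q: np.ndarray  # n x K posterior mean admixture
    P: np.ndarray  # K x L posterior mean presence-allele frequencies
    lnl_trace: np.ndarray
    ln_prob_data: float

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")


def fit_admixture(
    matrix: BinaryMarkerMatrix,
    K: int,
    burn_in: int = 5_000,
    iterations: int = 10_000,
    seed: int = 0,
    alpha: float = 1.0,
    drift: float = 0.05,
    sample_ancestral: bool = True,
) -> StructureRun:
    """One MCMC run at a fixed K.  ``iterations`` counts post-burn-in sweeps."""
    X = matrix.scores.astype(bool)
    n, L = X.shape
    if not 1 <= K <= n:
        raise ValueError("K must be between 1 and the number of individuals")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), K)))

    Q = rng.dirichlet(np.full(K, 1.0), size=n)
    p_anc = np.clip(X.mean(axis=0), 0.05, 0.95)
    P = np.clip(rng.beta(1, 1, size=(K, L)), 1e-3, 1 - 1e-3)
    F = drift
    prior_scale = (1 - F) / F

    present = X  # n x L boolean
    absent = ~X
    lnl_trace = np.empty(burn_in + iterations)
    Q_sum = np.zeros_like(Q)
    P_sum = np.zeros_like(P)

    for it in range(burn_in + iterations):
        # --- latent copy states -------------------------------------------
        W1 = Q[:, None, :] * P.T[None, :, :]  # n x L x K, presence from k
        W0 = Q[:, None, :] * (1 - P).T[None, :, :]
        s = W1.sum(axis=2)
        u = W0.sum(axis=2)

        # copy presence indicators (a1, a2): band absent -> both null;
        # band present -> (PP, PN, NP) with probs (s^2, su, us)/(s^2+2su)
        z_tot = s**2 + 2 * s * u
        r = rng.random((n, L))
        pp = s**2 / z_tot
        pn = s * u / z_tot
        a1 = present & (r < pp + pn)
        a2 = present & ((r < pp) | (r >= pp + pn))

        # cluster of origin per copy
        cum1 = np.cumsum(W1, axis=2)
        cum0 = np.cumsum(W0, axis=2)

        def sample_origin(is_presence):
            cum = np.where(is_presence[:, :, None], cum1, cum0)
            total = cum[:, :, -1]
            rr = rng.random((n, L)) * total
            return (cum < rr[:, :, None]).sum(axis=2)

        z1 = sample_origin(a1)
        z2 = sample_origin(a2)

        # --- counts --------------------------------------------------------
        n1 = np.empty((K, L))
        n0 = np.empty((K, L))
        origin_counts = np.empty((n, K))
        for k in range(K):
            in1 = (z1 == k) & a1
            in2 = (z2 == k) & a2
            nn1 = (z1 == k) & ~a1
            nn2 = (z2 == k) & ~a2
            n1[k] = in1.sum(axis=0) + in2.sum(axis=0)
            n0[k] = nn1.sum(axis=0) + nn2.sum(axis=0)
            origin_counts[:, k] = (z1 == k).sum(axis=1) + (z2 == k).sum(axis=1)

        # --- parameter updates ----------------------------------------------
        a0 = p_anc * prior_scale
        b0 = (1 - p_anc) * prior_scale
        P = np.clip(rng.beta(a0[None, :] + n1, b0[None, :] + n0), _EPS, 1 - _EPS)

        gam = rng.gamma(alpha + origin_counts)
        Q = gam / gam.sum(axis=1, keepdims=True)

        if sample_ancestral:
            prop = p_anc + rng.normal(0, 0.05, L)
            prop = np.abs(prop)  # reflect at 0
            prop = np.where(prop > 1, 2 - prop, prop)  # reflect at 1
            prop = np.clip(prop, 1e-3, 1 - 1e-3)

            def log_target(pa):
                a = pa * prior_scale
                b = (1 - pa) * prior_scale
                return (
                    (a - 1) * np.log(P) + (b - 1) * np.log(1 - P)
                ).sum(axis=0) - K * betaln(a, b)

            accept = np.log(rng.random(L)) < log_target(prop) - log_target(p_anc)
            p_anc = np.where(accept, prop, p_anc)

        # --- likelihood ------------------------------------------------------
        m = np.clip(Q @ P, _EPS, 1 - _EPS)
        p_absent = (1 - m) ** 2
        lnl = float(
            np.where(X, np.log1p(-p_absent), np.log(p_absent)).sum()
        )
        lnl_trace[it] = lnl
        if it >= burn_in:
            Q_sum += Q
            P_sum += P

    post = lnl_trace[burn_in:]
    ln_prob_data = float(post.mean() - post.var(ddof=1) / 2)
    Q_mean = Q_sum / iterations
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    return StructureRun(
        K=K,
        seed=seed,
        Q=Q_mean,
        P=P_sum / iterations,
        lnl_trace=lnl_trace,
        ln_prob_data=ln_prob_data,
    )


def align_labels(runs: list[StructureRun]) -> list[StructureRun]:
    """Permute cluster columns of each run to best match the first run
    (Hungarian assignment maximizing the Q-column match matrix)."""
    if not runs:
        return runs
    K = runs[0].K
    if any(r.K != K for r in runs):
        raise ValueError("runs must share K")
    if K == 1:
        return runs
    ref = runs[0].Q
    aligned = [runs[0]]
    for run in runs[1:]:
        M = ref.T @ run.Q  # K x K overlap
        rows, cols = linear_sum_assignment(-M)
        perm = np.empty(K, dtype=int)
        perm[rows] = cols
        aligned.append(
            StructureRun(
                K=run.K,
                seed=run.seed,
                Q=run.Q[:, perm],
                P=run.P[perm, :],
                lnl_trace=run.lnl_trace,
                ln_prob_data=run.ln_prob_data,
            )
        )
    return aligned


@dataclass
class EvannoTable:
    k_values: list[int]
    mean_ln_prob: dict[int, float]
    sd_ln_prob: dict[int, float]
    delta_k: dict[int, float | None]
    modal_k: int

    def to_dict(self) -> dict:
        return {
            "k_values": self.k_values,
            "mean_ln_prob": {str(k): v for k, v in self.mean_ln_prob.items()},
            "sd_ln_prob": {str(k): v for k, v in self.sd_ln_prob.items()},
            "delta_k": {str(k): v for k, v in self.delta_k.items()},
            "modal_k": self.modal_k,
        }


def evanno(runs: list[StructureRun]) -> EvannoTable:
    """Evanno DeltaK table over a set of multi-run results spanning K values.

    DeltaK is defined for interior K only; K with zero between-run sd get a
    missing DeltaK.  If no DeltaK is defined (or all are zero) the lowest K
    is reported as modal.
    """
    by_k: dict[int, list[float]] = {}
    for run in runs:
        by_k.setdefault(run.K, []).append(run.ln_prob_data)
    ks = sorted(by_k)
    if len(ks) < 3:
        raise ValueError("Evanno needs at least 3 consecutive K values")
    if any(len(v) < 2 for v in by_k.values()):
        raise ValueError("Evanno needs at least 2 runs per K")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    delta: dict[int, float | None] = {}
    for a, k, b in zip(ks, ks[1:], ks[2:]):
        if sd[k] == 0:
            delta[k] = None
            continue
        delta[k] = abs(mean[b] - 2 * mean[k] + mean[a]) / sd[k]
    defined = {k: v for k, v in delta.items() if v is not None}
    if defined and max(defined.values()) > 0:
        modal = max(defined, key=defined.get)
    else:
        modal = ks[0]
    return EvannoTable(
        k_values=ks, mean_ln_prob=mean, sd_ln_prob=sd, delta_k=delta, modal_k=modal
    )


def run_k_range(
    matrix: BinaryMarkerMatrix,
    k_min: int = 1,
    k_max: int = 4,
    n_runs: int = 5,
    burn_in: int = 5_000,
    iterations: int = 10_000,
    seed: int = 0,
    **kwargs,
) -> list[StructureRun]:
    """Independent MCMC runs across a K range (one derived seed per run)."""
    runs = []
    for K in range(k_min, k_max + 1):
        for rep in range(n_runs):
            run_seed = int(
                stage_rng(seed, f"admixture_K{K}_rep{rep}").integers(2**31)
            )
            runs.append(
                fit_admixture(
                    matrix, K, burn_in=burn_in, iterations=iterations,
                    seed=run_seed, **kwargs,
                )
            )
    return runs
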