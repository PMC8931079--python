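"""Bayesian admixture clustering of binary subepiloci.

The model is the haploid-Bernoulli analogue of the classic admixture
model: individual i has membership vector Q_i ~ Dirichlet(alpha * 1_K);
each binary column s of individual i picks a latent cluster of origin
Z_is ~ Categorical(Q_i) and emits X_is ~ Bernoulli(P_{Z_is, s}) with
cluster band frequencies P_ks ~ Beta(1, 1). A diploid genotype model
would double-count one-hot indicator columns, hence the haploid
emission.

Inference is a plain Gibbs sampler alternating Z | Q,P; P | Z,X;
Q | Z. The per-sweep log-likelihood log P(X | Z, P) is recorded after
burn-in; its mean across recorded sweeps is the L(K) estimate used by
the Evanno delta-K model-selection heuristic

    delta_K = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd_r L_r(K)

over replicate runs r.

Replicate runs of a mixture model are identified only up to a
permutation of cluster labels; :func:`align_runs` aligns each run to
the first by the column permutation maximizing the summed column-wise
dot products of the Q matrices (solved exactly as an assignment
problem).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .scoring import SubEpilociMatrix

__all__ = [
    "McmcParams",
    "StructureRun",
    "EvannoTable",
    "fit_structure",
    "structure_scan",
    "evanno_delta_k",
    "align_runs",
]


@dataclass(frozen=True)
class McmcParams:
    """Gibbs-sampler schedule: burn-in sweeps, kept sweeps, thinning."""

    burn_in: int = 5_000
    n_sweeps: int = 20_000
    thin: int = 10


@dataclass
class StructureRun:
    K: int
    individual_ids: list[str]
    Q: np.ndarray  # (N, K) posterior-mean membership proportions
    P: np.ndarray  # (K, S) posterior-mean band frequencies
    loglik_trace: np.ndarray  # per recorded sweep
    mean_loglik: float
    seed: int
    mcmc: McmcParams
    alpha: float = 1.0


def _as_matrix(sub) -> tuple[np.ndarray, list[str]]:
    if isinstance(sub, SubEpilociMatrix):
        return sub.B.astype(np.int8), list(sub.individual_ids)
    X = np.asarray(sub)
    return X.astype(np.int8), [str(i) for i in range(X.shape[0])]


def fit_structure(
    sub,
    K: int,
    mcmc: McmcParams = McmcParams(),
    seed: int = 0,
    alpha: float = 1.0,
) -> StructureRun:
    """Run the Gibbs sampler at a fixed cluster count K.

    ``sub`` is a :class:`SubEpilociMatrix` or a plain binary array
    (individuals x columns). Returns posterior means of Q and P over
    the recorded sweeps and the mean observed-data log-likelihood.
    Identical seed and parameters give bit-identical results.
    """
    X, ind_ids = _as_matrix(sub)
    if X.size == 0:
        raise ValueError("empty input matrix")
    if np.any((X != 0) & (X != 1)):
        raise ValueError("input matrix must be binary")
    N, S = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > N:
        raise ValueError(f"K={K} exceeds the number of individuals ({N})")

    rng = np.random.default_rng(seed)
    Xb = X.astype(bool)
    # init: P around column means with jitter, Q uniform
    colmean = np.clip(X.mean(axis=0), 0.05, 0.95)
    P = np.clip(
        colmean[None, :] + rng.uniform(-0.05, 0.05, size=(K, S)), 1e-3, 1 - 1e-3
    )
    Q = np.full((N, K), 1.0 / K)

    n_rec = 0
    Q_sum = np.zeros_like(Q)
    P_sum = np.zeros_like(P)
    trace: list[float] = []
    karange = np.arange(K)[None, :, None]

    total = mcmc.burn_in + mcmc.n_sweeps
    for sweep in range(total):
        # Z | Q, P  — weights w[i,k,s] = Q_ik * P_ks^x (1-P_ks)^(1-x)
        PX = np.where(Xb[:, None, :], P[None, :, :], 1.0 - P[None, :, :])
        W = Q[:, :, None] * PX
        cum = np.cumsum(W, axis=1)
        U = rng.random((N, 1, S)) * cum[:, -1:, :]
        Z = np.sum(U > cum, axis=1)  # (N, S) in 0..K-1

        Zoh = Z[:, None, :] == karange  # (N, K, S) one-hot
        # P | Z, X
        n1 = (Zoh & Xb[:, None, :]).sum(axis=0)
        ntot = Zoh.sum(axis=0)
        P = rng.beta(1.0 + n1, 1.0 + (ntot - n1))
        # Q | Z
        counts = Zoh.sum(axis=2)  # (N, K)
        gam = rng.standard_gamma(alpha + counts)
        Q = gam / gam.sum(axis=1, keepdims=True)

        if sweep >= mcmc.burn_in and (sweep - mcmc.burn_in) % mcmc.thin == 0:
            pz = np.take_along_axis(PX, Z[:, None, :], axis=1)[:, 0, :]
            ll = float(np.log(pz).sum())
            trace.append(ll)
            Q_sum += Q
            P_sum += P
            n_rec += 1

    if n_rec == 0:
        raise ValueError("MCMC schedule records no sweeps; increase n_sweeps")
    trace_arr = np.array(trace)
    if not np.all(np.isfinite(trace_arr)):
        raise RuntimeError("non-finite log-likelihood in trace")
    return StructureRun(
        K=K,
        individual_ids=ind_ids,
        Q=Q_sum / n_rec,
        P=P_sum / n_rec,
        loglik_trace=trace_arr,
        mean_loglik=float(trace_arr.mean()),
        seed=seed,
        mcmc=mcmc,
        alpha=alpha,
    )


def structure_scan(
    sub,
    k_range: range | list[int],
    replicates: int = 10,
    mcmc: McmcParams = McmcParams(),
    seed: int = 0,
    alpha: float = 1.0,
) -> list[StructureRun]:
    """Replicate runs over a range of K; per-run seeds derive from ``seed``."""
    runs = []
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(list(k_range)) * replicates))
    for K in k_range:
        for _ in range(replicates):
            child_seed = int(next(children).generate_state(1)[0] % (2**31))
            runs.append(fit_structure(sub, K, mcmc=mcmc, seed=child_seed, alpha=alpha))
    return runs


@dataclass
class EvannoTable:
    """Per-K likelihood summaries and delta-K; ``best_K`` maximizes delta_K."""

    table: pd.DataFrame  # index K: mean_L, sd_L, L_prime, L_doubleprime, delta_K
    best_K: int | None = field(default=None)


def evanno_delta_k(runs: list[StructureRun]) -> EvannoTable:
    """Evanno second-order rate-of-change table from replicate runs.

    Requires >= 3 consecutive K values with >= 2 replicates each and
    equal replicate counts (excess replicates beyond the minimum are
    dropped per K, pairing replicates by order). Rows where sd(L) = 0
    get delta_K = NaN and are flagged, not dropped; best_K is the
    argmax over defined rows.
    """
    by_k: dict[int, list[float]] = {}
    for run in runs:
        by_k.setdefault(run.K, []).append(run.mean_loglik)
    ks = sorted(by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    n_rep = min(len(v) for v in by_k.values())
    if n_rep < 2:
        raise ValueError("need >= 2 replicates per K")
    L = np.array([by_k[k][:n_rep] for k in ks])  # (nK, n_rep)
    mean_L = L.mean(axis=1)
    sd_L = L.std(axis=1, ddof=1)

    rows = []
    for idx, k in enumerate(ks):
        row = {
            "K": k,
            "mean_L": mean_L[idx],
            "sd_L": sd_L[idx],
            "L_prime": np.nan,
            "L_doubleprime": np.nan,
            "delta_K": np.nan,
            "sd_zero": False,
        }
        if idx >= 1:
            row["L_prime"] = mean_L[idx] - mean_L[idx - 1]
        if 1 <= idx <= len(ks) - 2:
            lpp = np.abs(L[idx + 1] - 2.0 * L[idx] + L[idx - 1]).mean()
            row["L_doubleprime"] = lpp
            if sd_L[idx] > 0:
                row["delta_K"] = lpp / sd_L[idx]
            else:
                row["sd_zero"] = True
        rows.append(row)
    table = pd.DataFrame(rows).set_index("K")
    defined = table["delta_K"].dropna()
    if defined.empty:
        raise ValueError("delta_K undefined for every interior K (sd_L all zero)")
    return EvannoTable(table=table, best_K=int(defined.idxmax()))


def align_runs(
    runs: list[StructureRun],
) -> tuple[list[StructureRun], np.ndarray]:
    """Align replicate runs of equal K to the first run's cluster labels.

    For each run the column permutation of Q maximizing the summed
    column-wise dot products with the reference Q is found by solving
    the (K x K) assignment problem exactly, then applied to Q and P.
    Returns the aligned runs (new objects; the first is unchanged) and
    the element-wise mean Q.
    """
    if not runs:
        raise ValueError("no runs to align")
    K = runs[0].K
    shape = runs[0].Q.shape
    for run in runs:
        if run.K != K or run.Q.shape != shape:
            raise ValueError("runs differ in K or shape")
    ref = runs[0].Q
    aligned = [runs[0]]
    for run in runs[1:]:
        score = ref.T @ run.Q  # score[a, b] = ref_a . run_b
        rr, cc = linear_sum_assignment(-score)
        perm = np.empty(K, dtype=int)
        perm[rr] = cc  # reference column a takes run column perm[a]
        aligned.append(
            StructureRun(
                K=run.K,
                individual_ids=run.individual_ids,
                Q=run.Q[:, perm],
                P=run.P[perm, :],
                loglik_trace=run.loglik_trace,
                mean_loglik=run.mean_loglik,
                seed=run.seed,
                mcmc=run.mcmc,
                alpha=run.alpha,
            )
        )
    mean_Q = np.mean([r.Q for r in aligned], axis=0)
    return aligned, mean_Q
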