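"""One-level analysis of molecular variance (AMOVA) on squared distances.

The variance of a set of multivariate points equals the mean of
pairwise squared distances divided by twice the count, so AMOVA
partitions squared inter-individual distances without ever forming
coordinates:

    SS_total  = (1/N) * sum_{i<j} d2_ij
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d2_ij
    SS_among  = SS_total - SS_within

with degrees of freedom G-1 and N-G. Variance components follow the
standard unbalanced-design estimator with

    n0 = (N - sum_g n_g^2 / N) / (G - 1)

(sigma2_within = MS_within; sigma2_among = (MS_among - MS_within)/n0)
and Phi_st = sigma2_among / sigma2_total, tested by permuting
individuals among groups with group sizes held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PopulationMap
from .scoring import SubEpilociMatrix

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "squared_euclidean_distances",
    "amova",
    "variance_components_from_ss",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of *squared* pairwise distances, zero diagonal."""

    individual_ids: list[str]
    D2: np.ndarray

    def __post_init__(self) -> None:
        self.D2 = np.asarray(self.D2, dtype=float)
        n = len(self.individual_ids)
        if self.D2.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.D2, self.D2.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.D2) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.D2 < 0):
            raise ValueError("squared distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def distances(self) -> np.ndarray:
        """Plain (non-squared) Euclidean distances."""
        return np.sqrt(self.D2)


def squared_euclidean_distances(sub: SubEpilociMatrix) -> DistanceMatrix:
    """Pairwise squared Euclidean distance between individuals.

    On 0/1 subepiloci this is the Hamming count of differing columns.
    """
    X = sub.B.astype(float)
    sq = (X**2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    D2 = np.maximum(D2, 0.0)
    np.fill_diagonal(D2, 0.0)
    D2 = (D2 + D2.T) / 2.0
    return DistanceMatrix(individual_ids=list(sub.individual_ids), D2=D2)


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    df_total: int
    SS_among: float
    SS_within: float
    SS_total: float
    MS_among: float
    MS_within: float
    sigma2_among: float
    sigma2_within: float
    sigma2_total: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None
    n_permutations: int
    seed: int | None

    def table(self) -> pd.DataFrame:
        """Report table mirroring the conventional AMOVA layout."""
        phi_report = max(self.phi_st, 0.0)
        return pd.DataFrame(
            [
                {
                    "source": "Among groups",
                    "df": self.df_among,
                    "SS": self.SS_among,
                    "est_var": self.sigma2_among,
                    "pct": self.pct_among,
                    "phi_st": phi_report,
                    "p_value": self.p_value,
                },
                {
                    "source": "Within groups",
                    "df": self.df_within,
                    "SS": self.SS_within,
                    "est_var": self.sigma2_within,
                    "pct": self.pct_within,
                    "phi_st": np.nan,
                    "p_value": np.nan,
                },
                {
                    "source": "Total",
                    "df": self.df_total,
                    "SS": self.SS_total,
                    "est_var": self.sigma2_total,
                    "pct": 100.0,
                    "phi_st": np.nan,
                    "p_value": np.nan,
                },
            ]
        )


def variance_components_from_ss(
    ss_among: float, ss_within: float, group_sizes: list[int] | np.ndarray
) -> dict:
    """Variance components, percentages and Phi_st from SS and group sizes.

    This is the estimator step alone; it lets printed ANOVA tables
    (df, SS) be converted to components without the raw data.
    """
    ns = np.asarray(group_sizes, dtype=float)
    G = ns.size
    N = ns.sum()
    df_among = int(G - 1)
    df_within = int(N - G)
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (N - (ns**2).sum() / N) / (G - 1)
    sigma2_among = (ms_among - ms_within) / n0
    sigma2_within = ms_within
    sigma2_total = sigma2_among + sigma2_within
    if sigma2_among < 0:
        warnings.warn("negative among-group variance component (reported as-is)")
    phi = sigma2_among / sigma2_total if sigma2_total > 0 else 0.0
    return {
        "df_among": df_among,
        "df_within": df_within,
        "MS_among": ms_among,
        "MS_within": ms_within,
        "n0": n0,
        "sigma2_among": sigma2_among,
        "sigma2_within": sigma2_within,
        "sigma2_total": sigma2_total,
        "pct_among": 100.0 * sigma2_among / sigma2_total if sigma2_total > 0 else 0.0,
        "pct_within": 100.0 * sigma2_within / sigma2_total if sigma2_total > 0 else 0.0,
        "phi_st": phi,
    }


def _ss_partition(D2: np.ndarray, labels: np.ndarray, sizes: np.ndarray) -> tuple:
    N = D2.shape[0]
    ss_total = D2[np.triu_indices(N, k=1)].sum() / N
    ss_within = 0.0
    for g, n_g in enumerate(sizes):
        idx = np.flatnonzero(labels == g)
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * n_g)
    return ss_total, ss_within


def amova(
    dist: DistanceMatrix,
    pops: PopulationMap,
    n_perm: int = 9999,
    seed: int | None = None,
) -> AmovaResult:
    """One-level AMOVA with a permutation test for Phi_st.

    ``n_perm`` random relabelings of individuals (group sizes fixed)
    give p = (b + 1) / (n_perm + 1) where b counts permuted Phi_st >=
    observed — the observed configuration counts in both numerator and
    denominator. ``n_perm=0`` skips the test (p is None). Requires >= 2
    groups with >= 2 individuals each. If all individuals are
    identical (SS_total = 0) Phi_st is reported as 0 with a warning.
    """
    labels = pops.labels_for(dist.individual_ids)
    G = len(pops.groups)
    if G < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    sizes = np.bincount(labels, minlength=G)
    if np.any(sizes < 2):
        small = pops.groups[int(np.argmin(sizes))]
        raise ValueError(f"group {small!r} has fewer than 2 individuals")
    N = dist.n
    D2 = dist.D2

    ss_total, ss_within = _ss_partition(D2, labels, sizes)
    ss_among = ss_total - ss_within
    df_among, df_within = G - 1, N - G

    if ss_total <= 0:
        warnings.warn("all individuals identical; Phi_st undefined, reported as 0")
        comp = {
            "MS_among": 0.0,
            "MS_within": 0.0,
            "sigma2_among": 0.0,
            "sigma2_within": 0.0,
            "sigma2_total": 0.0,
            "pct_among": 0.0,
            "pct_within": 0.0,
            "phi_st": 0.0,
        }
        p_value = None if n_perm == 0 else 1.0
        return AmovaResult(
            df_among=df_among,
            df_within=df_within,
            df_total=N - 1,
            SS_among=ss_among,
            SS_within=ss_within,
            SS_total=ss_total,
            p_value=p_value,
            n_permutations=n_perm,
            seed=seed,
            **comp,
        )

    comp = variance_components_from_ss(ss_among, ss_within, sizes)
    phi_obs = comp["phi_st"]

    p_value: float | None = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        n0 = comp["n0"]
        b = 0
        perm_labels = labels.copy()
        for _ in range(n_perm):
            rng.shuffle(perm_labels)
            st, sw = _ss_partition(D2, perm_labels, sizes)
            sa = st - sw
            ms_a = sa / df_among
            ms_w = sw / df_within
            s2a = (ms_a - ms_w) / n0
            s2t = s2a + ms_w
            phi_p = s2a / s2t if s2t > 0 else 0.0
            if phi_p >= phi_obs - 1e-12:
                b += 1
        p_value = (b + 1) / (n_perm + 1)

    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        df_total=N - 1,
        SS_among=ss_among,
        SS_within=ss_within,
        SS_total=ss_total,
        MS_among=comp["MS_among"],
        MS_within=comp["MS_within"],
        sigma2_among=comp["sigma2_among"],
        sigma2_within=comp["sigma2_within"],
        sigma2_total=comp["sigma2_total"],
        pct_among=comp["pct_among"],
        pct_within=comp["pct_within"],
        phi_st=phi_obs,
        p_value=p_value,
        n_permutations=n_perm,
        seed=seed,
    )
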