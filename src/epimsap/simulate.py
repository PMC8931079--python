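"""Synthetic MSAP datasets with known ground truth.

The generator emulates a regional survey design: ``n_groups`` sampled
regions of ``n_per_group`` individuals, fragment loci spread over a
set of selective primer pairs, and a latent subpopulation structure
shared by regions. For each latent subpopulation k and locus l a
methylation-type probability vector

    theta_kl ~ Dirichlet(dirichlet_alpha * base_type_probs)

is drawn; every individual of a region assigned to subpopulation k
draws its type at l from Categorical(theta_kl). Types map to (H, M)
band pairs (I -> 1/1, II -> 0/1, III -> 1/0, IV -> 0/0) and each band
is then flipped independently with ``noise_flip_prob``, mimicking
scoring error (noise acts on bands, not types, so it can create any
type). ``dirichlet_alpha`` controls between-subpopulation
differentiation: large alpha pins theta to ``base_type_probs``
everywhere (Phi_st -> 0), small alpha lets subpopulations diverge.

Defaults reproduce the survey geometry the pipeline targets: 5 regions
x 10 individuals, 8 primer pairs totalling 551 loci, mean type
proportions ~ (51.5, 16, 14, 18.5)% and moderate differentiation
(Phi_st ~ 0.085 with two latent subpopulations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .io import PairedBandMatrix, PopulationMap

__all__ = ["SyntheticConfig", "generate", "calibrate_differentiation"]

# Per-primer-pair locus counts of the emulated survey (total 551).
DEFAULT_PRIMER_PAIRS: dict[str, int] = {
    "E36/M42": 74,
    "E36/M50": 68,
    "E40/M40": 68,
    "E40/M50": 67,
    "E83/M40": 51,
    "E83/M42": 84,
    "E83/M59": 65,
    "E85/M42": 74,
}

DEFAULT_GROUPS = ("FZ", "CHY", "JSJ", "XS", "WC")

# Two latent subpopulations splitting the regions along the
# north-east / south-west axis of the emulated survey.
DEFAULT_GROUP_TO_SUBPOP = {"FZ": 1, "CHY": 1, "JSJ": 1, "XS": 2, "WC": 2}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; ``seed`` is mandatory for reproducibility."""

    seed: int
    n_groups: int = 5
    n_per_group: int = 10
    group_names: tuple[str, ...] = DEFAULT_GROUPS
    primer_pairs: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PRIMER_PAIRS)
    )
    group_to_subpop: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_TO_SUBPOP)
    )
    # frozen by a one-off calibration of Phi_st to the ~0.085 regime
    dirichlet_alpha: float = 6.15
    base_type_probs: tuple[float, float, float, float] = (0.515, 0.16, 0.14, 0.185)
    noise_flip_prob: float = 0.01
    fragment_length_range: tuple[int, int] = (37, 495)

    def __post_init__(self) -> None:
        p = np.asarray(self.base_type_probs, dtype=float)
        if p.size != 4 or np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("base_type_probs must be 4 positive values summing to 1")
        if self.n_groups < 1 or self.n_per_group < 1:
            raise ValueError("counts must be positive")
        if len(self.group_names) < self.n_groups:
            raise ValueError("not enough group names")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if not 0.0 <= self.noise_flip_prob < 1.0:
            raise ValueError("noise_flip_prob must be in [0, 1)")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.group_names[: self.n_groups])

    @property
    def n_loci(self) -> int:
        return sum(self.primer_pairs.values())


# type code -> (H, M) band pair
_TYPE_TO_BANDS = np.array([[1, 1], [0, 1], [1, 0], [0, 0]], dtype=np.int8)


def generate(
    config: SyntheticConfig,
) -> tuple[PairedBandMatrix, PopulationMap, dict]:
    """Draw one synthetic dataset; returns (bands, population map, truth).

    The truth record holds the latent subpopulation of every group,
    per-individual true types before noise, the theta array and the
    seed; it is meant for recovery tests and is never read by the
    analysis modules.
    """
    rng = np.random.default_rng(config.seed)
    groups = config.groups
    subpop_of_group = {
        g: config.group_to_subpop.get(g, 1) for g in groups
    }
    subpops = sorted(set(subpop_of_group.values()))
    sp_index = {sp: k for k, sp in enumerate(subpops)}
    L = config.n_loci
    base = np.asarray(config.base_type_probs)

    theta = rng.dirichlet(config.dirichlet_alpha * base, size=(len(subpops), L))

    individual_ids: list[str] = []
    assignments: dict[str, str] = {}
    sp_of_ind: list[int] = []
    for g in groups:
        for r in range(config.n_per_group):
            ind = f"{g}_{r + 1:02d}"
            individual_ids.append(ind)
            assignments[ind] = g
            sp_of_ind.append(sp_index[subpop_of_group[g]])
    n = len(individual_ids)

    # per-individual per-locus type draw from theta of its subpopulation
    probs = theta[np.array(sp_of_ind)]  # (n, L, 4)
    u = rng.random((n, L, 1))
    types = (u > np.cumsum(probs, axis=2)).sum(axis=2).astype(np.int8)

    bands = _TYPE_TO_BANDS[types]  # (n, L, 2) -> H, M
    H, M = bands[:, :, 0].copy(), bands[:, :, 1].copy()
    if config.noise_flip_prob > 0:
        flipH = rng.random((n, L)) < config.noise_flip_prob
        flipM = rng.random((n, L)) < config.noise_flip_prob
        H = np.where(flipH, 1 - H, H)
        M = np.where(flipM, 1 - M, M)

    lo, hi = config.fragment_length_range
    if hi - lo + 1 < max(config.primer_pairs.values()):
        raise ValueError("fragment_length_range too narrow for distinct lengths")
    locus_ids: list[str] = []
    for pp, count in config.primer_pairs.items():
        # lengths distinct within a primer pair so locus ids are unique
        lengths = np.sort(rng.choice(np.arange(lo, hi + 1), size=count, replace=False))
        locus_ids.extend(f"{pp}_{ln}" for ln in lengths)

    pbm = PairedBandMatrix(
        individual_ids=individual_ids, locus_ids=locus_ids, H=H, M=M
    )
    pops = PopulationMap(assignments=assignments, groups=list(groups))
    truth = {
        "seed": config.seed,
        "subpop_of_group": subpop_of_group,
        "subpop_of_individual": dict(
            zip(individual_ids, [subpops[k] for k in sp_of_ind])
        ),
        "theta": theta,
        "true_types": types,
        "dirichlet_alpha": config.dirichlet_alpha,
    }
    return pbm, pops, truth


def write_truth(truth: dict, path) -> None:
    """Persist the truth record (theta/type arrays as nested lists)."""
    payload = dict(truth)
    payload["theta"] = np.asarray(truth["theta"]).tolist()
    payload["true_types"] = np.asarray(truth["true_types"]).tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _measure_phi(config: SyntheticConfig, n_seeds: int) -> float:
    """Mean AMOVA Phi_st of generated data over derived seeds."""
    from .amova import amova, squared_euclidean_distances
    from .scoring import classify_methylation, mixed_score

    phis = []
    for k in range(n_seeds):
        cfg = replace(config, seed=(config.seed + 7919 * k) % (2**31))
        pbm, pops, _ = generate(cfg)
        sub = mixed_score(classify_methylation(pbm))
        res = amova(squared_euclidean_distances(sub), pops, n_perm=0)
        phis.append(res.phi_st)
    return float(np.mean(phis))


def calibrate_differentiation(
    config: SyntheticConfig,
    target_phi: float,
    tolerance: float,
    alpha_bounds: tuple[float, float] = (1.0, 5000.0),
    n_seeds: int = 5,
    max_iter: int = 40,
) -> SyntheticConfig:
    """Tune ``dirichlet_alpha`` so generated data hit a target Phi_st.

    Phi_st decreases monotonically (in expectation) with alpha, so a
    bisection on log(alpha) converges; the measured Phi_st is averaged
    over ``n_seeds`` datasets. Raises if the bounds do not bracket the
    target or if the tolerance is not reached within ``max_iter``.
    """
    if not 0.0 < target_phi < 0.5:
        raise ValueError("target_phi must be in (0, 0.5)")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    lo, hi = alpha_bounds
    phi_lo = _measure_phi(replace(config, dirichlet_alpha=lo), n_seeds)
    phi_hi = _measure_phi(replace(config, dirichlet_alpha=hi), n_seeds)
    # phi decreases with alpha: need phi(lo) >= target >= phi(hi)
    if not (phi_lo >= target_phi >= phi_hi):
        raise ValueError(
            f"alpha bounds {alpha_bounds} do not bracket Phi_st={target_phi} "
            f"(measured {phi_lo:.4f} at {lo}, {phi_hi:.4f} at {hi})"
        )
    for _ in range(max_iter):
        mid = float(np.exp((np.log(lo) + np.log(hi)) / 2.0))
        phi_mid = _measure_phi(replace(config, dirichlet_alpha=mid), n_seeds)
        if abs(phi_mid - target_phi) <= tolerance:
            return replace(config, dirichlet_alpha=mid)
        if phi_mid > target_phi:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"calibration did not reach |Phi_st - {target_phi}| <= {tolerance} "
        f"in {max_iter} iterations"
    )
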