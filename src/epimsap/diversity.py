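"""Per-group diversity indices and Nei identity/distance on subepiloci.

Subepiloci are one-hot binary state indicators, so the band frequency
of a subepilocus within a group is used directly as its allele
frequency (no dominant-marker null-allele correction is offered: it
would be wrong on one-hot data). For a subepilocus with band
frequency p, q = 1 - p:

* Nei's gene diversity      h  = 1 - (p^2 + q^2)
* effective allele number   Ne = 1 / (p^2 + q^2)
* Shannon's index (nats)    I  = -(p ln p + q ln q)

Indices are averaged over *all* subepiloci (monomorphic included).
PLP% is the percentage of subepiloci with 0 < p < 1 within the group.

Nei's normalized identity between groups x and y uses the mean gene
identities J_xy = mean_s[p_x p_y + q_x q_y], J_x = mean_s[p_x^2 + q_x^2]:
I_xy = J_xy / sqrt(J_x J_y), and distance D = -ln I_xy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PopulationMap
from .scoring import SubEpilociMatrix

__all__ = [
    "DiversityIndices",
    "NeiMatrix",
    "band_frequencies",
    "diversity_indices",
    "nei_identity_distance",
]


@dataclass
class DiversityIndices:
    """Per-group diversity table: N, n_loci_used, PLP%, Ne, I, h."""

    table: pd.DataFrame


@dataclass
class NeiMatrix:
    """Pairwise Nei identity and distance between groups."""

    groups: list[str]
    identity: pd.DataFrame
    distance: pd.DataFrame

    def combined_table(self) -> pd.DataFrame:
        """Identity below the diagonal, distance above (report layout)."""
        out = pd.DataFrame(
            np.full((len(self.groups),) * 2, np.nan),
            index=self.groups,
            columns=self.groups,
        )
        for a, ga in enumerate(self.groups):
            for b, gb in enumerate(self.groups):
                if a > b:
                    out.iloc[a, b] = self.identity.iloc[a, b]
                elif a < b:
                    out.iloc[a, b] = self.distance.iloc[a, b]
        return out


def band_frequencies(sub: SubEpilociMatrix, pops: PopulationMap) -> pd.DataFrame:
    """Within-group band frequency per subepilocus (groups x subepiloci)."""
    labels = np.array([pops.group_of(i) for i in sub.individual_ids])
    rows = []
    for g in pops.groups:
        mask = labels == g
        if not mask.any():
            raise ValueError(f"group {g!r} has no individuals")
        rows.append(sub.B[mask].mean(axis=0))
    return pd.DataFrame(rows, index=pops.groups, columns=sub.subepilocus_ids)


def _per_column_indices(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(h, Ne, I) per column for frequency vector p; 0 ln 0 taken as 0."""
    q = 1.0 - p
    homo = p**2 + q**2
    h = 1.0 - homo
    ne = 1.0 / homo
    with np.errstate(divide="ignore", invalid="ignore"):
        ilog = -(
            np.where(p > 0, p * np.log(p), 0.0) + np.where(q > 0, q * np.log(q), 0.0)
        )
    return h, ne, ilog


def diversity_indices(sub: SubEpilociMatrix, pops: PopulationMap) -> DiversityIndices:
    """Per-group PLP%, mean Ne, mean I and mean h over all subepiloci."""
    freqs = band_frequencies(sub, pops)
    sizes = pops.group_sizes()
    rows = []
    for g in pops.groups:
        p = freqs.loc[g].to_numpy()
        h, ne, ilog = _per_column_indices(p)
        rows.append(
            {
                "group": g,
                "N": sizes[g],
                "n_loci_used": p.size,
                "PLP_percent": 100.0 * np.mean((p > 0) & (p < 1)),
                "Ne_mean": ne.mean(),
                "I_mean": ilog.mean(),
                "h_mean": h.mean(),
            }
        )
    return DiversityIndices(table=pd.DataFrame(rows).set_index("group"))


def nei_identity_distance(sub: SubEpilociMatrix, pops: PopulationMap) -> NeiMatrix:
    """Nei's normalized identity I_xy and distance D = -ln I_xy per group pair."""
    if len(pops.groups) < 2:
        raise ValueError("Nei identity needs at least 2 groups")
    freqs = band_frequencies(sub, pops).to_numpy()
    q = 1.0 - freqs
    G = freqs.shape[0]
    J_within = (freqs**2 + q**2).mean(axis=1)
    identity = np.ones((G, G))
    for a in range(G):
        for b in range(a + 1, G):
            j_xy = (freqs[a] * freqs[b] + q[a] * q[b]).mean()
            val = j_xy / np.sqrt(J_within[a] * J_within[b])
            if val <= 0:  # impossible for binary frequencies
                raise AssertionError("non-positive Nei identity")
            identity[a, b] = identity[b, a] = val
    with np.errstate(divide="ignore"):
        distance = -np.log(identity)
    np.fill_diagonal(distance, 0.0)
    groups = list(pops.groups)
    return NeiMatrix(
        groups=groups,
        identity=pd.DataFrame(identity, index=groups, columns=groups),
        distance=pd.DataFrame(distance, index=groups, columns=groups),
    )
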