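"""Methylation-type scoring of paired MSAP band matrices.

Each (H, M) band pair at a cell is classified into one of four
methylation types, following the standard HpaII/MspI interpretation:

===== ======= ==========================================  ======
type  (H, M)  biochemical reading                         degree
===== ======= ==========================================  ======
I     (1, 1)  unmethylated CCGG                           0
II    (0, 1)  full methylation of the internal cytosine   1
III   (1, 0)  hemimethylation of the external cytosine    1
IV    (0, 0)  methylation of both/external cytosines,     2
              or site mutation
===== ======= ==========================================  ======

"Mixed scoring" expands each multistate epilocus into four binary
indicator subepiloci (I -> 1000, II -> 0100, III -> 0010, IV -> 0001),
so that frequency-based population statistics apply unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .io import MsapFormatError, PairedBandMatrix, PopulationMap

__all__ = [
    "TYPE_LABELS",
    "TYPE_DEGREE",
    "MethylationTypeMatrix",
    "SubEpilociMatrix",
    "MethylationLevelSummary",
    "LocusAccounting",
    "classify_methylation",
    "mixed_score",
    "methylation_levels",
    "derive_levels",
    "anova_duncan",
    "duncan_critical_range",
    "locus_accounting",
]

TYPE_LABELS = ("I", "II", "III", "IV")
TYPE_DEGREE = (0, 1, 1, 2)


@dataclass
class MethylationTypeMatrix:
    """Per-cell methylation type codes (0..3 for types I..IV)."""

    individual_ids: list[str]
    locus_ids: list[str]
    codes: np.ndarray  # (n, L) int8 in {0,1,2,3}

    @property
    def types(self) -> np.ndarray:
        """String type labels, same shape as ``codes``."""
        return np.array(TYPE_LABELS, dtype=object)[self.codes]

    @property
    def degree(self) -> np.ndarray:
        """Methylation degree per cell: 0 (type I), 1 (II/III), 2 (IV)."""
        return np.array(TYPE_DEGREE, dtype=np.int8)[self.codes]

    def to_bands(self) -> PairedBandMatrix:
        """Invert the typing back to the (H, M) band pair."""
        H = np.isin(self.codes, (0, 2)).astype(np.int8)  # types I, III
        M = np.isin(self.codes, (0, 1)).astype(np.int8)  # types I, II
        return PairedBandMatrix(
            individual_ids=list(self.individual_ids),
            locus_ids=list(self.locus_ids),
            H=H,
            M=M,
        )


@dataclass
class SubEpilociMatrix:
    """Binary one-hot expansion: 4 indicator subepiloci per locus.

    ``B`` has shape (n_individuals, 4 * n_loci); within each locus
    block of 4 columns (order I, II, III, IV) exactly one entry per
    row is 1.
    """

    individual_ids: list[str]
    subepilocus_ids: list[str]
    B: np.ndarray

    @property
    def n_subepiloci(self) -> int:
        return self.B.shape[1]

    def drop_type_columns(self, drop: str = "I") -> "SubEpilociMatrix":
        """Remove one indicator column per locus (default the type-I one).

        The 4 columns of a locus are linearly dependent (they sum to 1);
        dropping one leaves 3 informative columns per locus, which is the
        default encoding fed to the structure sampler.
        """
        if drop not in TYPE_LABELS:
            raise ValueError(f"unknown methylation type {drop!r}")
        keep = [
            j
            for j, s in enumerate(self.subepilocus_ids)
            if s.rpartition(":")[2] != drop
        ]
        return SubEpilociMatrix(
            individual_ids=list(self.individual_ids),
            subepilocus_ids=[self.subepilocus_ids[j] for j in keep],
            B=self.B[:, keep].copy(),
        )


def classify_methylation(bands: PairedBandMatrix) -> MethylationTypeMatrix:
    """Type each (H, M) cell: (1,1)->I, (0,1)->II, (1,0)->III, (0,0)->IV."""
    codes = ((1 - bands.H) + 2 * (1 - bands.M)).astype(np.int8)
    return MethylationTypeMatrix(
        individual_ids=list(bands.individual_ids),
        locus_ids=list(bands.locus_ids),
        codes=codes,
    )


def mixed_score(types: MethylationTypeMatrix) -> SubEpilociMatrix:
    """Expand each epilocus into 4 binary subepiloci (one-hot per cell)."""
    n, L = types.codes.shape
    B = np.zeros((n, 4 * L), dtype=np.int8)
    cols = 4 * np.arange(L)[None, :] + types.codes
    B[np.arange(n)[:, None], cols] = 1
    sub_ids = [f"{loc}:{t}" for loc in types.locus_ids for t in TYPE_LABELS]
    return SubEpilociMatrix(
        individual_ids=list(types.individual_ids),
        subepilocus_ids=sub_ids,
        B=B,
    )


# ---------------------------------------------------------------------------
# Methylation levels (group percentages, ANOVA, Duncan letters)
# ---------------------------------------------------------------------------

_LEVEL_NAMES = ("total", "full", "hemi", "non")


@dataclass
class MethylationLevelSummary:
    """Per-group methylation-type percentages and derived levels.

    ``type_pct`` has one row per group with columns I..IV (percent of
    all (individual, locus) cells of the group). ``levels`` holds the
    derived total/full/hemi/non percentages under the selected
    convention; ``per_individual`` retains one row per individual for
    the group-comparison ANOVA; ``letters``/``anova_p`` hold Duncan's
    compact letter display and the one-way ANOVA p per statistic.
    """

    convention: str
    type_pct: pd.DataFrame
    levels: pd.DataFrame
    per_individual: pd.DataFrame
    letters: pd.DataFrame
    anova_p: pd.Series


def derive_levels(pct: pd.DataFrame, convention: str) -> pd.DataFrame:
    """Derived levels from type percentages (columns I..IV).

    Under ``convention="printed"`` full = II + IV and hemi = III (the
    internal-cytosine reading); under ``convention="footnote"``
    full = III + IV and hemi = II. Total = II + III + IV and
    non = I in both.
    """
    if convention == "printed":
        full, hemi = pct["II"] + pct["IV"], pct["III"]
    elif convention == "footnote":
        full, hemi = pct["III"] + pct["IV"], pct["II"]
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return pd.DataFrame(
        {
            "total": pct["II"] + pct["III"] + pct["IV"],
            "full": full,
            "hemi": hemi,
            "non": pct["I"],
        }
    )


def methylation_levels(
    types: MethylationTypeMatrix,
    pops: PopulationMap,
    convention: str = "printed",
    alpha: float = 0.05,
) -> MethylationLevelSummary:
    """Group methylation-type percentages, derived levels and Duncan letters.

    Percentages are over all (individual, locus) cells of a group, so
    with equal locus counts they equal the mean of per-individual
    percentages. A one-way ANOVA across groups plus Duncan's multiple
    range test (on per-individual level vectors) is run for each
    derived statistic.
    """
    n, L = types.codes.shape
    labels = np.array([pops.group_of(i) for i in types.individual_ids])

    # per-individual type percentages
    counts = np.stack([(types.codes == c).sum(axis=1) for c in range(4)], axis=1)
    ind_pct = pd.DataFrame(
        100.0 * counts / L, index=types.individual_ids, columns=list(TYPE_LABELS)
    )
    per_individual = derive_levels(ind_pct, convention)
    per_individual.insert(0, "group", labels)

    group_pct = ind_pct.groupby(labels).mean().reindex(pops.groups)
    levels = derive_levels(group_pct, convention)

    letters = {}
    anova_p = {}
    for stat in _LEVEL_NAMES:
        vals = per_individual[stat].to_numpy(dtype=float)
        res = anova_duncan(vals, labels, alpha=alpha, group_order=pops.groups)
        letters[stat] = pd.Series(res["letters"])
        anova_p[stat] = res["p_value"]
    return MethylationLevelSummary(
        convention=convention,
        type_pct=group_pct,
        levels=levels,
        per_individual=per_individual,
        letters=pd.DataFrame(letters).reindex(pops.groups),
        anova_p=pd.Series(anova_p),
    )


@lru_cache(maxsize=4096)
def _studentized_q(prob: float, span: int, df_err: int) -> float:
    # ppf is expensive; identical (span, df) pairs recur across calls
    return float(stats.studentized_range.ppf(prob, span, df_err))


def duncan_critical_range(
    span: int, df_err: int, ms_err: float, n_harmonic: float, alpha: float
) -> float:
    """Duncan's least significant range for means ``span`` ranks apart.

    Uses the studentized range at Duncan's protection level
    ``1 - (1 - alpha)**(span - 1)``.
    """
    protect = 1.0 - (1.0 - alpha) ** (span - 1)
    q = _studentized_q(1.0 - protect, span, df_err)
    return float(q * np.sqrt(ms_err / n_harmonic))


def anova_duncan(
    values: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    group_order: list[str] | None = None,
) -> dict:
    """One-way ANOVA plus Duncan's multiple range test with letter display.

    Returns a dict with ``F``, ``p_value`` and ``letters`` (group ->
    compact letter string; groups sharing a letter do not differ at
    ``alpha``). Requires >= 2 groups with >= 2 observations each. If
    the within-group mean square is zero, groups with equal means share
    a letter and unequal means get distinct letters.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if group_order is None:
        _, first = np.unique(labels, return_index=True)
        group_order = list(labels[np.sort(first)])
    groups = [values[labels == g] for g in group_order]
    if len(groups) < 2:
        raise ValueError("Duncan's test needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")

    N = values.size
    G = len(groups)
    means = np.array([g.mean() for g in groups])
    ns = np.array([len(g) for g in groups])
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_err = N - G
    ms_err = ss_within / df_err
    if ms_err > 0:
        F, p = stats.f_oneway(*groups)
    else:
        # degenerate: no within-group variation
        F = np.inf if np.ptp(means) > 0 else 0.0
        p = 0.0 if np.ptp(means) > 0 else 1.0
    n_h = G / np.sum(1.0 / ns)  # harmonic mean group size

    order = np.argsort(means, kind="stable")  # ties: group-order stable
    sorted_means = means[order]

    def differ(i: int, j: int) -> bool:
        """Significant difference between sorted ranks i <= j."""
        span = j - i + 1
        diff = sorted_means[j] - sorted_means[i]
        if ms_err == 0:
            return diff > 0
        return diff > duncan_critical_range(span, df_err, ms_err, n_h, alpha)

    # maximal non-significant runs over the sorted means -> letters
    runs: list[tuple[int, int]] = []
    i = 0
    while i < G:
        j = i
        while j + 1 < G and not differ(i, j + 1):
            j += 1
        if not runs or runs[-1][1] < j:
            runs.append((i, j))
        i += 1
    letters_sorted = ["" for _ in range(G)]
    for r, (a, b) in enumerate(runs):
        letter = chr(ord("a") + r)
        for k in range(a, b + 1):
            letters_sorted[k] += letter
    letters = {group_order[order[k]]: letters_sorted[k] for k in range(G)}
    return {"F": float(F), "p_value": float(p), "letters": letters}


# ---------------------------------------------------------------------------
# Per-primer-pair locus accounting
# ---------------------------------------------------------------------------


@dataclass
class LocusAccounting:
    """Per-primer-pair and total locus counts.

    ``table`` columns: primer_pair, length_min, length_max, n_amplified,
    n_polymorphic, pct_polymorphic, n_methylation, n_nonmethylation;
    the last row is the total.
    """

    table: pd.DataFrame
    polymorphic_definition: str

    @property
    def totals(self) -> pd.Series:
        return self.table.iloc[-1]


def locus_accounting(
    bands: PairedBandMatrix,
    types: MethylationTypeMatrix | None = None,
    polymorphic: str = "joint",
    methylation_rule: str = "any",
) -> LocusAccounting:
    """Count amplified, polymorphic and methylation loci per primer pair.

    A locus is a *methylation locus* iff at least one individual shows
    a methylated type there: under ``methylation_rule="any"`` (default)
    that is any of II/III/IV; under ``"differential"`` only the
    HpaII/MspI differential types II/III count, so loci varying purely
    between presence (I) and absence (IV) are treated as AFLP-like
    genetic polymorphisms rather than methylation-susceptible loci.
    (Under the ``"any"`` rule a nonmethylation locus is all type I and
    hence monomorphic, so polymorphic nonmethylated loci can only
    exist under ``"differential"``.)

    A locus is *polymorphic* iff its banding pattern varies across
    individuals — under the default ``polymorphic="joint"`` the joint
    (H, M) pattern is compared; ``"hpa"``/``"msp"`` compare a single
    digest's pattern (the literature does not pin the definition down,
    so it is explicit here).
    """
    if types is None:
        types = classify_methylation(bands)
    if polymorphic == "joint":
        poly = (np.ptp(bands.H, axis=0) > 0) | (np.ptp(bands.M, axis=0) > 0)
    elif polymorphic == "hpa":
        poly = np.ptp(bands.H, axis=0) > 0
    elif polymorphic == "msp":
        poly = np.ptp(bands.M, axis=0) > 0
    else:
        raise ValueError(f"unknown polymorphic definition {polymorphic!r}")
    if methylation_rule == "any":
        meth = (types.codes > 0).any(axis=0)
    elif methylation_rule == "differential":
        meth = np.isin(types.codes, (1, 2)).any(axis=0)
    else:
        raise ValueError(f"unknown methylation rule {methylation_rule!r}")

    pps = np.array([bands.primer_pair_of_locus[l] for l in bands.locus_ids])
    lengths = np.array([bands.fragment_length_of_locus[l] for l in bands.locus_ids])
    rows = []
    for pp in bands.primer_pairs():
        m = pps == pp
        n_amp = int(m.sum())
        n_poly = int(poly[m].sum())
        n_meth = int(meth[m].sum())
        rows.append(
            {
                "primer_pair": pp,
                "length_min": int(lengths[m].min()),
                "length_max": int(lengths[m].max()),
                "n_amplified": n_amp,
                "n_polymorphic": n_poly,
                "pct_polymorphic": 100.0 * n_poly / n_amp,
                "n_methylation": n_meth,
                "n_nonmethylation": n_amp - n_meth,
            }
        )
    total_amp = len(bands.locus_ids)
    rows.append(
        {
            "primer_pair": "Total",
            "length_min": int(lengths.min()),
            "length_max": int(lengths.max()),
            "n_amplified": total_amp,
            "n_polymorphic": int(poly.sum()),
            "pct_polymorphic": 100.0 * int(poly.sum()) / total_amp,
            "n_methylation": int(meth.sum()),
            "n_nonmethylation": total_amp - int(meth.sum()),
        }
    )
    return LocusAccounting(table=pd.DataFrame(rows), polymorphic_definition=polymorphic)
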