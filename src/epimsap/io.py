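"""Reading and writing of MSAP band matrices, population maps and trees.

The raw observation of an MSAP experiment is a pair of binary band
matrices over the same individuals and fragment loci: one for the
EcoRI/HpaII digest ("H") and one for the EcoRI/MspI digest ("M").
Locus identifiers encode the selective primer pair and the fragment
length in base pairs, e.g. ``E36/M42_147``.

File formats
------------
* Band matrix CSV: first column ``id`` (individual label), remaining
  column headers are locus ids, cells are 0/1. One file per digest.
* Population map: two-column CSV/TSV with header ``id,group``.
* Trees: Newick with branch lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MsapFormatError",
    "PairedBandMatrix",
    "PopulationMap",
    "read_band_matrices",
    "write_band_matrices",
    "read_population_map",
    "write_population_map",
    "write_newick",
]


class MsapFormatError(ValueError):
    """Raised when an input file violates the band-matrix or map format."""


def _parse_locus_id(locus_id: str) -> tuple[str, int]:
    """Split ``primerpair_lengthbp`` into (primer pair, fragment length)."""
    head, sep, tail = locus_id.rpartition("_")
    if not sep or not head:
        raise MsapFormatError(
            f"locus id {locus_id!r} does not follow 'primerpair_lengthbp'"
        )
    try:
        length = int(tail)
    except ValueError:
        raise MsapFormatError(
            f"locus id {locus_id!r} has non-integer fragment length {tail!r}"
        ) from None
    if length <= 0:
        raise MsapFormatError(f"locus id {locus_id!r} has non-positive length")
    return head, length


@dataclass
class PairedBandMatrix:
    """Aligned H (EcoRI/HpaII) and M (EcoRI/MspI) presence/absence matrices.

    ``H`` and ``M`` are (n_individuals, n_loci) arrays of 0/1 with
    identical row and column orderings given by ``individual_ids`` and
    ``locus_ids``.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    H: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.int8)
        self.M = np.asarray(self.M, dtype=np.int8)
        n, L = len(self.individual_ids), len(self.locus_ids)
        if self.H.shape != (n, L) or self.M.shape != (n, L):
            raise MsapFormatError(
                f"matrix shapes {self.H.shape}/{self.M.shape} do not match "
                f"{n} individuals x {L} loci"
            )
        for name, labels in (
            ("individual", self.individual_ids),
            ("locus", self.locus_ids),
        ):
            seen: set[str] = set()
            for lab in labels:
                if lab in seen:
                    raise MsapFormatError(f"duplicate {name} label {lab!r}")
                seen.add(lab)
        for name, mat in (("H", self.H), ("M", self.M)):
            bad = np.argwhere((mat != 0) & (mat != 1))
            if bad.size:
                i, j = bad[0]
                raise MsapFormatError(
                    f"non-binary cell in {name} at individual "
                    f"{self.individual_ids[i]!r}, locus {self.locus_ids[j]!r}"
                )
        # locus ids must parse; cache metadata maps
        self.primer_pair_of_locus = {}
        self.fragment_length_of_locus = {}
        for loc in self.locus_ids:
            pp, ln = _parse_locus_id(loc)
            self.primer_pair_of_locus[loc] = pp
            self.fragment_length_of_locus[loc] = ln

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def primer_pairs(self) -> list[str]:
        """Primer-pair labels in first-appearance (column) order."""
        out: list[str] = []
        for loc in self.locus_ids:
            pp = self.primer_pair_of_locus[loc]
            if pp not in out:
                out.append(pp)
        return out

    def filter_fragment_length(self, min_bp: int, max_bp: int) -> "PairedBandMatrix":
        """Return a copy keeping only loci with length in [min_bp, max_bp]."""
        keep = [
            j
            for j, loc in enumerate(self.locus_ids)
            if min_bp <= self.fragment_length_of_locus[loc] <= max_bp
        ]
        return PairedBandMatrix(
            individual_ids=list(self.individual_ids),
            locus_ids=[self.locus_ids[j] for j in keep],
            H=self.H[:, keep].copy(),
            M=self.M[:, keep].copy(),
        )


@dataclass
class PopulationMap:
    """Individual -> group assignment; groups in first-appearance order."""

    assignments: dict[str, str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assignments:
            raise MsapFormatError("population map is empty")
        if not self.groups:
            seen: list[str] = []
            for g in self.assignments.values():
                if g not in seen:
                    seen.append(g)
            self.groups = seen

    def group_of(self, individual: str) -> str:
        try:
            return self.assignments[individual]
        except KeyError:
            raise MsapFormatError(
                f"individual {individual!r} missing from population map"
            ) from None

    def members(self, group: str) -> list[str]:
        return [i for i, g in self.assignments.items() if g == group]

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.members(g)) for g in self.groups}

    def labels_for(self, individual_ids: list[str]) -> np.ndarray:
        """Integer group index per individual (order of ``self.groups``)."""
        idx = {g: k for k, g in enumerate(self.groups)}
        return np.array([idx[self.group_of(i)] for i in individual_ids])


def _read_one_band_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2 or df.columns[0] != "id":
        raise MsapFormatError(
            f"{path}: band matrix must start with an 'id' column and have "
            "at least one locus column"
        )
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise MsapFormatError(f"{path}: duplicate individual label {dup!r}")
    df = df.set_index("id")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise MsapFormatError(f"{path}: duplicate locus label {dup!r}")
    return df


def read_band_matrices(
    path_H,
    path_M,
    missing: str = "reject",
    fragment_length_range: tuple[int, int] | None = None,
) -> PairedBandMatrix:
    """Load an H/M CSV pair into a validated :class:`PairedBandMatrix`.

    Row and column order is taken from the H file; the M file is
    reindexed to match. ``missing`` is the policy for NA cells:
    ``"reject"`` (default) raises, ``"drop-locus"`` removes any locus
    with a missing cell in either matrix. ``fragment_length_range``
    optionally keeps only loci within ``[min, max]`` bp (off by
    default; fragment-size selection is an explicit analysis choice).
    """
    if missing not in ("reject", "drop-locus"):
        raise ValueError(f"unknown missing policy {missing!r}")
    dfH = _read_one_band_csv(path_H)
    dfM = _read_one_band_csv(path_M)
    for lab in dfH.index:
        if lab not in dfM.index:
            raise MsapFormatError(f"individual {lab!r} present in H but not in M")
    for lab in dfM.index:
        if lab not in dfH.index:
            raise MsapFormatError(f"individual {lab!r} present in M but not in H")
    for lab in dfH.columns:
        if lab not in dfM.columns:
            raise MsapFormatError(f"locus {lab!r} present in H but not in M")
    for lab in dfM.columns:
        if lab not in dfH.columns:
            raise MsapFormatError(f"locus {lab!r} present in M but not in H")
    dfM = dfM.reindex(index=dfH.index, columns=dfH.columns)

    na_mask = dfH.isna().any(axis=0) | dfM.isna().any(axis=0)
    if na_mask.any():
        if missing == "reject":
            loc = dfH.columns[na_mask][0]
            raise MsapFormatError(f"missing cell(s) at locus {loc!r}")
        dfH = dfH.loc[:, ~na_mask]
        dfM = dfM.loc[:, ~na_mask]

    pbm = PairedBandMatrix(
        individual_ids=list(dfH.index),
        locus_ids=list(dfH.columns),
        H=dfH.to_numpy(),
        M=dfM.to_numpy(),
    )
    if fragment_length_range is not None:
        pbm = pbm.filter_fragment_length(*fragment_length_range)
    return pbm


def write_band_matrices(bands: PairedBandMatrix, path_H, path_M) -> None:
    """Write the H and M matrices as band-matrix CSV files."""
    for path, mat in ((path_H, bands.H), (path_M, bands.M)):
        df = pd.DataFrame(mat, index=bands.individual_ids, columns=bands.locus_ids)
        df.index.name = "id"
        df.to_csv(path)


def read_population_map(path) -> PopulationMap:
    """Read a two-column ``id,group`` file (comma or tab separated)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise MsapFormatError(f"{path}: population map needs id and group columns")
    if df.empty:
        raise MsapFormatError(f"{path}: population map is empty")
    ids, groups = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise MsapFormatError(f"{path}: individual {dup!r} listed twice")
    return PopulationMap(assignments=dict(zip(ids, groups)))


def write_population_map(pops: PopulationMap, path) -> None:
    df = pd.DataFrame(
        {"id": list(pops.assignments), "group": list(pops.assignments.values())}
    )
    df.to_csv(path, index=False)


def write_newick(tree, path) -> None:
    """Serialize an :class:`~epimsap.ordination.NJTree` to a Newick file."""
    for length in tree.branch_lengths():
        if not math.isfinite(length):
            raise ValueError(f"non-finite branch length {length!r} in tree")
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
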