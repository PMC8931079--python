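"""End-to-end orchestration of the MSAP analysis.

``run_pipeline`` executes scoring -> methylation levels / locus
accounting -> diversity -> Nei -> AMOVA -> PCoA -> NJ -> structure ->
Evanno on either loaded band matrices or a synthetic dataset, writing
one TSV per result table plus the Newick tree, the structure Q
matrices and a run log. All randomness derives from one master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as msap_io
from .amova import amova, squared_euclidean_distances
from .diversity import diversity_indices, nei_identity_distance
from .ordination import nj_tree, pcoa
from .scoring import classify_methylation, locus_accounting, methylation_levels, mixed_score
from .simulate import SyntheticConfig, generate, write_truth
from .structure import McmcParams, align_runs, evanno_delta_k, structure_scan

__all__ = ["RunConfig", "run_pipeline", "make_report"]

REPORT_FILES = [
    "locus_accounting.tsv",
    "methylation_levels.tsv",
    "diversity.tsv",
    "nei.tsv",
    "amova.tsv",
    "pcoa.tsv",
    "tree.nwk",
    "evanno.tsv",
    "run_log.json",
]


@dataclass
class RunConfig:
    """Pipeline settings; exactly one of (input paths, synthetic) is used."""

    outdir: str
    seed: int = 0
    # either explicit inputs ...
    path_H: str | None = None
    path_M: str | None = None
    path_popmap: str | None = None
    # ... or a synthetic block (dict of SyntheticConfig overrides)
    synthetic: dict | None = None
    convention: str = "printed"
    fragment_length_range: tuple[int, int] | None = None
    n_perm: int = 9999
    nj_level: str = "individual"  # or "group" (Nei distance between groups)
    k_min: int = 1
    k_max: int = 5
    replicates: int = 3
    mcmc: McmcParams = field(default_factory=lambda: McmcParams(500, 2000, 5))
    structure_drop_type: str | None = "I"
    run_structure: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "mcmc" in raw and isinstance(raw["mcmc"], dict):
            raw["mcmc"] = McmcParams(**raw["mcmc"])
        if "fragment_length_range" in raw and raw["fragment_length_range"]:
            raw["fragment_length_range"] = tuple(raw["fragment_length_range"])
        return cls(**raw)

    def validate(self) -> None:
        paths = (self.path_H, self.path_M, self.path_popmap)
        any_path = any(p is not None for p in paths)
        all_paths = all(p is not None for p in paths)
        if (any_path and self.synthetic is not None) or not (
            all_paths or self.synthetic is not None
        ):
            raise ValueError(
                "exactly one of (path_H/path_M/path_popmap) or a synthetic "
                "block must be given"
            )
        if any_path and not all_paths:
            raise ValueError("path_H, path_M and path_popmap must all be given")


def _tsv(df: pd.DataFrame, path: Path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle into ``config.outdir``.

    Returns a dict of the in-memory results keyed by stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.SeedSequence(config.seed)
    amova_seed, structure_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(2)
    )
    log: dict = {"seed": config.seed, "convention": config.convention}

    if config.synthetic is not None:
        syn = dict(config.synthetic)
        syn.setdefault("seed", config.seed)
        scfg = SyntheticConfig(**syn)
        bands, pops, truth = generate(scfg)
        write_truth(truth, outdir / "truth.json")
        msap_io.write_band_matrices(bands, outdir / "bands_H.csv", outdir / "bands_M.csv")
        msap_io.write_population_map(pops, outdir / "popmap.csv")
        log["input"] = {"synthetic": {**syn, "dirichlet_alpha": scfg.dirichlet_alpha}}
    else:
        bands = msap_io.read_band_matrices(
            config.path_H,
            config.path_M,
            fragment_length_range=config.fragment_length_range,
        )
        pops = msap_io.read_population_map(config.path_popmap)
        log["input"] = {"H": str(config.path_H), "M": str(config.path_M)}
    if config.fragment_length_range is not None and config.synthetic is not None:
        bands = bands.filter_fragment_length(*config.fragment_length_range)
    log["fragment_length_range"] = config.fragment_length_range
    log["n_individuals"] = bands.n_individuals
    log["n_loci"] = bands.n_loci

    results: dict = {"bands": bands, "pops": pops}

    types = classify_methylation(bands)
    sub = mixed_score(types)
    results["types"], results["sub"] = types, sub
    log["n_subepiloci"] = sub.n_subepiloci

    acct = locus_accounting(bands, types)
    _tsv(
        acct.table.set_index("primer_pair"),
        outdir / "locus_accounting.tsv",
        [f"polymorphic definition: {acct.polymorphic_definition}"],
    )
    results["locus_accounting"] = acct

    levels = methylation_levels(types, pops, convention=config.convention)
    tab = pd.concat([levels.type_pct, levels.levels], axis=1)
    for stat in levels.letters.columns:
        tab[f"{stat}_letters"] = levels.letters[stat]
    _tsv(
        tab,
        outdir / "methylation_levels.tsv",
        [
            f"convention: {config.convention}",
            "anova p-values: "
            + ", ".join(f"{k}={v:.4g}" for k, v in levels.anova_p.items()),
        ],
    )
    results["levels"] = levels

    div = diversity_indices(sub, pops)
    _tsv(div.table, outdir / "diversity.tsv", ["means over all subepiloci"])
    results["diversity"] = div

    nei = nei_identity_distance(sub, pops)
    _tsv(
        nei.combined_table(),
        outdir / "nei.tsv",
        ["identity below diagonal, distance above"],
    )
    results["nei"] = nei

    dist = squared_euclidean_distances(sub)
    am = amova(dist, pops, n_perm=config.n_perm, seed=amova_seed)
    _tsv(
        am.table().set_index("source"),
        outdir / "amova.tsv",
        [f"permutations: {config.n_perm}, seed: {amova_seed}"],
    )
    results["amova"] = am
    log["amova_seed"] = amova_seed

    pc = pcoa(dist)
    frame = pc.frame()
    _tsv(
        frame,
        outdir / "pcoa.tsv",
        [
            "pct variance per axis: "
            + ", ".join(f"{v:.2f}" for v in pc.pct_variance[: frame.shape[1]])
        ],
    )
    results["pcoa"] = pc

    if config.nj_level == "group":
        tree = nj_tree(nei.distance.to_numpy(), leaf_names=list(nei.groups))
    else:
        tree = nj_tree(dist)
    msap_io.write_newick(tree, outdir / "tree.nwk")
    results["tree"] = tree

    if config.run_structure:
        X = sub.drop_type_columns(config.structure_drop_type) if config.structure_drop_type else sub
        runs = structure_scan(
            X,
            range(config.k_min, config.k_max + 1),
            replicates=config.replicates,
            mcmc=config.mcmc,
            seed=structure_seed,
        )
        by_k: dict[int, list] = {}
        for run in runs:
            by_k.setdefault(run.K, []).append(run)
        for K, kruns in by_k.items():
            aligned, mean_Q = align_runs(kruns)
            for r, run in enumerate(aligned):
                df = pd.DataFrame(
                    run.Q,
                    index=run.individual_ids,
                    columns=[f"cluster{c + 1}" for c in range(K)],
                )
                _tsv(df, outdir / f"structure_K{K}_run{r + 1}.tsv", [f"seed: {run.seed}"])
            df = pd.DataFrame(
                mean_Q,
                index=kruns[0].individual_ids,
                columns=[f"cluster{c + 1}" for c in range(K)],
            )
            _tsv(df, outdir / f"structure_K{K}_mean.tsv")
        ev = evanno_delta_k(runs)
        _tsv(ev.table, outdir / "evanno.tsv", [f"best_K: {ev.best_K}"])
        results["structure_runs"] = runs
        results["evanno"] = ev
        log["structure_seed"] = structure_seed
        log["best_K"] = ev.best_K
        log["mcmc"] = dataclasses.asdict(config.mcmc)
        log["structure_drop_type"] = config.structure_drop_type

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    results["log"] = log
    return results


def make_report(outdir) -> str:
    """Collate the result TSVs of a finished run into one markdown summary.

    Raises FileNotFoundError naming the first missing bundle file.
    Writes ``report.md`` in the bundle directory and returns the text.
    """
    outdir = Path(outdir)
    required = [f for f in REPORT_FILES if f != "run_log.json"]
    missing = [f for f in required + ["run_log.json"] if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(f"bundle incomplete, missing: {', '.join(missing)}")
    sections = {
        "Locus accounting": "locus_accounting.tsv",
        "Methylation levels": "methylation_levels.tsv",
        "Diversity indices": "diversity.tsv",
        "Nei identity / distance": "nei.tsv",
        "AMOVA": "amova.tsv",
    }
    lines = ["# MSAP analysis report", ""]
    log = json.loads((outdir / "run_log.json").read_text())
    lines.append(
        f"{log['n_individuals']} individuals, {log['n_loci']} loci, "
        f"{log['n_subepiloci']} subepiloci; master seed {log['seed']}."
    )
    lines.append("")
    for title, fname in sections.items():
        lines.append(f"## {title}")
        lines.append("")
        lines.append("```")
        lines.append((outdir / fname).read_text().rstrip())
        lines.append("```")
        lines.append("")
    ev_path = outdir / "evanno.tsv"
    if ev_path.exists():
        best = ev_path.read_text().splitlines()[0].replace("# ", "")
        lines.append(f"## Structure\n\nEvanno delta-K: {best}")
        lines.append("")
    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    return text
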