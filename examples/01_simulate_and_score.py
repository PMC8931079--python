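"""Generate a synthetic MSAP survey and score its methylation types.

Draws the default design (5 regions x 10 individuals, 8 primer pairs,
551 fragment loci), classifies every (HpaII, MspI) band pair into
methylation types I-IV, expands the epiloci into binary subepiloci,
and prints the per-region methylation levels with Duncan letters.
"""

from epimsap import (
    SyntheticConfig,
    classify_methylation,
    generate,
    locus_accounting,
    methylation_levels,
    mixed_score,
)

bands, pops, truth = generate(SyntheticConfig(seed=1))
print(f"{bands.n_individuals} individuals x {bands.n_loci} loci, "
      f"groups: {', '.join(pops.groups)}")

types = classify_methylation(bands)
sub = mixed_score(types)
print(f"mixed scoring: {bands.n_loci} epiloci -> {sub.n_subepiloci} subepiloci")

acct = locus_accounting(bands, types)
print("\nPer-primer-pair locus accounting (last row = totals):")
print(acct.table.round(1).to_string(index=False))

levels = methylation_levels(types, pops)
tab = levels.levels.round(2)
for stat in ("total", "full", "hemi", "non"):
    tab[stat] = tab[stat].astype(str) + levels.letters[stat]
print("\nMethylation levels (%) per region; shared letters = not "
      "significantly different (Duncan, alpha 0.05):")
print(tab.to_string())
print("\n'total' = % of cells in any methylated state (types II+III+IV); "
      "'full' = internal-cytosine methylation (II+IV); 'hemi' = III.")
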