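"""Within-region diversity indices and between-region Nei distances.

On the subepiloci matrix, computes per-region PLP%, effective allele
number Ne, Shannon's I and Nei's gene diversity h, then Nei's
normalized identity and distance between regions.
"""

from epimsap import (
    SyntheticConfig,
    classify_methylation,
    diversity_indices,
    generate,
    mixed_score,
    nei_identity_distance,
)

bands, pops, _ = generate(SyntheticConfig(seed=1))
sub = mixed_score(classify_methylation(bands))

div = diversity_indices(sub, pops)
print("Diversity per region (means over all subepiloci):")
print(div.table.round(3).to_string())
print("\nPLP% = share of subepiloci segregating within the region; "
      "h in [0, 0.5] and Ne in [1, 2] for binary markers.")

nei = nei_identity_distance(sub, pops)
print("\nNei identity (below diagonal) / distance (above diagonal):")
print(nei.combined_table().round(3).to_string())
most = nei.distance.stack().idxmax()
print(f"\nLargest epigenetic distance: {most[0]}-{most[1]} "
      f"(D = {nei.distance.loc[most]:.3f}); D = -ln(identity).")
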