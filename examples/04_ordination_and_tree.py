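"""Ordination (PCoA) and neighbour-joining trees of the survey.

PCoA embeds the individual distance matrix; the NJ tree is built both
at individual level (Euclidean distances on subepiloci) and at group
level (Nei distance between regions).
"""

from epimsap import (
    SyntheticConfig,
    classify_methylation,
    generate,
    mixed_score,
    nei_identity_distance,
    nj_tree,
    pcoa,
    squared_euclidean_distances,
)

bands, pops, _ = generate(SyntheticConfig(seed=1))
sub = mixed_score(classify_methylation(bands))
dist = squared_euclidean_distances(sub)

pc = pcoa(dist)
print("PCoA, % variance of first three axes: "
      + ", ".join(f"{v:.2f}" for v in pc.pct_variance[:3]))
coords = pc.frame().iloc[:, :2]
centroids = coords.groupby([pops.group_of(i) for i in coords.index]).mean()
print("\nRegion centroids on the first two axes:")
print(centroids.round(2).to_string())

tree = nj_tree(dist)
print(f"\nIndividual-level NJ tree: {len(tree.leaf_names)} leaves; "
      f"Newick starts: {tree.to_newick()[:60]}...")

nei = nei_identity_distance(sub, pops)
group_tree = nj_tree(nei.distance.to_numpy(), leaf_names=list(nei.groups))
print(f"Group-level NJ tree on Nei distances: {group_tree.to_newick()}")
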