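"""Correlation and clustering structure of the signature panel.

Pairwise Pearson correlation of the panel genes, an average-linkage
dendrogram on cosine distance (exported as Newick), and a fuzzy c-means
partition of the samples into two soft clusters on the z-scored panel.
"""

import lsmsurv as L

dataset = L.simulate(L.paperlike_config(seed=1))
panel = [f"LSM{i}" for i in range(1, 9)]

corr = L.gene_correlation(dataset.expression, panel)
long = corr.to_long()
strongest = long.loc[long["r"].abs().idxmax()]
print(long.round(3).head(8).to_string(index=False))
print(f"\nstrongest pair: {strongest.gene_a}-{strongest.gene_b} "
      f"r = {strongest.r:.2f} (planted block correlation ~0.45)")

link = L.cluster_genes_cosine(dataset.expression, panel)
print("\ncosine dendrogram:", L.dendrogram_to_newick(link, panel))

part = L.fuzzy_cluster_samples(dataset.expression, panel, seed=1)
n1 = (part.hard_label == 1).sum()
print(f"\nfuzzy c-means: {n1} vs {len(part.sample_ids) - n1} samples; "
      f"memberships sum to 1 per sample (converged in {part.n_iter} sweeps)")
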