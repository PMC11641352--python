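"""Cluster a compound library and pick each cluster's representative.

Builds a synthetic MACCS fingerprint library with six planted chemical
families (20 molecules each, 5% deletion noise), runs the full chain —
3-D t-SNE embedding on Jaccard distances, Ward agglomeration, cut at k=6,
Tanimoto medoid per cluster — and compares the result with the planted
ground truth.
"""

from tgvscreen import (
    EmbeddingConfig,
    cluster_fingerprints,
    gen_fingerprint_library,
    select_all,
)

lib = gen_fingerprint_library(k=6, m=20, flip_prob=0.05, seed=42)
assignment, embedding = cluster_fingerprints(
    list(lib.fingerprints), list(lib.ids), EmbeddingConfig(seed=42), k=6
)

agree = sum(
    1
    for a in set(lib.true_labels.values())
    for members in [{m for m, c in lib.true_labels.items() if c == a}]
    if len({assignment.labels[m] for m in members}) == 1
)
print(f"planted clusters kept intact: {agree} of 6")

reps = select_all(assignment, dict(zip(lib.ids, lib.fingerprints)))
print("cluster  representative  mean Tanimoto to cluster mates")
for rep in reps:
    print(f"{rep.cluster:>7}  {rep.molecule_id:>14}  {rep.mean_similarity:.3f}")

# A mean similarity near 0.9 means the representative shares ~95% of its
# substructure keys with a typical cluster mate ((1-p)/(1+p) at p=0.05);
# all six planted families intact means the embedding+cut recovered the
# true chemical classes.
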