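"""Cluster a small real SMILES library from scratch.

Ten molecules from two obvious chemical families — aliphatic alcohols and
substituted benzenes — are fingerprinted (MACCS, 166 keys), embedded and
cut at k=2.  With such clean structure the two families separate exactly.
"""

from tgvscreen import EmbeddingConfig, Molecule, cluster_pipeline

library = [
    Molecule("etoh", "ethanol", "CCO"),
    Molecule("proh", "1-propanol", "CCCO"),
    Molecule("buoh", "1-butanol", "CCCCO"),
    Molecule("peoh", "1-pentanol", "CCCCCO"),
    Molecule("glyc", "glycerol", "OCC(O)CO"),
    Molecule("benz", "benzene", "c1ccccc1"),
    Molecule("tol", "toluene", "Cc1ccccc1"),
    Molecule("phen", "phenol", "Oc1ccccc1"),
    Molecule("anil", "aniline", "Nc1ccccc1"),
    Molecule("xyl", "p-xylene", "Cc1ccc(C)cc1"),
]

assignment, embedding = cluster_pipeline(
    library, scheme="maccs", config=EmbeddingConfig(seed=7, perplexity=3), k=2
)

for cluster in (1, 2):
    members = [m.name for m in library if assignment.labels[m.id] == cluster]
    print(f"cluster {cluster}: {', '.join(members)}")

# Expected: one cluster holds the five alcohols, the other the five
# aromatics — the MACCS keys for aromatic rings dominate the Tanimoto
# distances between the families.
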