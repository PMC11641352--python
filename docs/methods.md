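# Methods

## Fingerprints and similarity

Molecules enter as SMILES (`.smi` files, `SMILES id [name]` per line,
`#` comments). Every string is parsed into a molecular graph with RDKit
before fingerprinting, so different entry forms of one structure give one
fingerprint. Two schemes are supported:

* `maccs` (default): the 166 MACCS substructure keys. RDKit emits a
  167-position vector whose index 0 is a placeholder; it is stripped so the
  fingerprint length is exactly 166.
* `hashed`: a 2048-bit Morgan (circular, radius 2) fingerprint.

Similarity is the Tanimoto coefficient on set bits. All-zero fingerprints
are rejected at construction rather than defining 0/0 := 0 or 1; chemically
meaningful molecules always set keys, and rejecting the degenerate case
keeps the coefficient total on its domain. The similarity matrix is
computed by one integer matrix product (bit intersections) plus row-count
arithmetic, and is exactly symmetric with unit diagonal.

## 3-D embedding

t-SNE embeds the compounds into three dimensions. The high-dimensional
affinities follow the standard construction — per-point Gaussian bandwidths
found by bisection so each conditional distribution's entropy equals
log(perplexity), then symmetrization — and the low-dimensional kernel is
Student-t with one degree of freedom, optimized by momentum gradient
descent with an early-exaggeration phase. scikit-learn's exact-method
implementation provides this; the embedding is bit-reproducible for a fixed
seed. Two distance inputs are available: Jaccard distance 1 − Tanimoto on
the fingerprints (default, consistent with the Tanimoto-centric screen) or
Euclidean distance on the raw bit vectors.

Parameter defaults and their reasons:

* **perplexity 30**, auto-capped to (n−1)/3 when the library is small. The
  cap is the feasibility bound of the bandwidth calibration.
* **learning rate `"auto"` = n / early-exaggeration, floored at 1.** With
  unit-scale Jaccard distances and libraries of one or two hundred
  compounds, fixed rates in the hundreds make the exact-method optimizer
  diverge (KL stuck above 1 after 1000 iterations and visibly shredded
  clusters); the adaptive rule keeps the exaggeration-phase step size
  proportional to the data and converges to KL < 0.05 on the same inputs.
  A fixed numeric rate can still be passed.
* **1000 iterations, early exaggeration 12 (first 250 iterations)** —
  standard published settings; convergence is monitored in tests through
  recovery metrics rather than the raw KL.
* **Zero distances** between duplicate molecules get 1e-10 of additive
  jitter so bandwidth calibration never divides by zero; duplicates simply
  co-locate.

Caveat: scikit-learn's exact method squares a precomputed distance matrix
*in place*; the embedding function always hands it a copy.

## Hierarchical clustering

Agglomeration is implemented directly with Lance–Williams updates on the
full Euclidean distance matrix of the embedded points, for four linkages
(single, complete, average, Ward). Writing it out — rather than calling a
library — pins down two things the toolkit's determinism contract needs:
ties between equally close pairs break by the smallest (left, right)
cluster creation index, and the merge record uses a fixed indexing (leaves
0..n−1 in input order, merge t creates cluster n+t). The implementation is
tested against a naive oracle that re-derives every cluster-pair distance
from the raw points at every step, and against SciPy's linkage heights.

Cutting at k undoes the last k−1 merges; clusters are numbered 1..k by
their smallest leaf index. k defaults to 6 — the number of classes the
motivating screen reported — but is an ordinary parameter; no automatic
model selection is attempted. Ward on the 3-D coordinates is the default
linkage, the usual choice for compact chemical families.

## Representative selection

The representative of a cluster is its Tanimoto medoid: the member with the
highest arithmetic-mean similarity to the other members, self excluded
(singletons represent themselves with mean 1.0). Ties break to the
lexicographically smallest molecule id. Similarity is computed within the
cluster only. Whether the mean includes self-similarity does not affect the
argmax (it shifts every mean by the same affine map) but does change the
reported value; the self-excluded convention is used throughout.

## Network pharmacology

Gene symbols are upper-cased and whitespace-trimmed tokens; alias
resolution would require live databases and is deliberately absent.
Score-carrying disease-gene records survive the merge filter only when
score > threshold (strict, threshold 5 by default, an `inclusive` switch
for ≥); unscored records always survive. Hubness is plain degree on the
undirected PPI graph, ties broken by symbol — degree is what "top hub
genes" means in the common Cytoscape workflow, and no other centrality is
offered. Enrichment is the one-sided hypergeometric upper tail
P(X ≥ k) with Benjamini–Hochberg adjustment across terms; the universe
defaults to all genes in the annotation (GMT) file unless supplied
explicitly, and the query must be contained in the universe.

## Energetics

Docking screening is a minimum over finite energies with deterministic
tie-breaking (molecule id, then target id). MM/PBSA aggregation derives
ΔG_gas = ΔE_vdw + ΔE_ele and ΔG_total = ΔG_gas + ΔG_solv per snapshot
*before* averaging, so the component identities hold to float precision in
every report; dispersion is the sample (n−1) standard deviation, the
convention of MM/PBSA reporting tools. Table-facing totals are rounded
half-even at 2 decimals. The bundled reference tables are checked with a
tolerance of 0.01 kcal/mol because tables whose gas/total columns were
rounded independently of their components can disagree with the recomputed
sums by exactly one ulp of the printed precision — half of the bundled rows
do.

Hydrogen-bond occupancy of a (donor, acceptor) pair is the percentage of
frames containing the pair at least once; the mean bonds-per-frame counts
every record. A pair occurring twice in one frame therefore counts once
toward occupancy and twice toward the rate. CSV inputs normalize the
Unicode minus (U+2212, and en/em dashes) to ASCII, since transcribed
energy tables routinely carry it.

## Synthetic fixtures

The generators define the conditions the tests run under:

* **Planted fingerprint libraries** (default k=6 clusters × m=20 members,
  166 bits, 5 % noise): each cluster owns a contiguous block of ~bits/k
  positions; prototypes switch on their own block's bits with probability
  0.6 and foreign bits with 0.02, so prototypes are nearly disjoint.
  Members delete each prototype bit independently with probability p
  (deletion noise), giving expected within-cluster Tanimoto
  (1−p)/(1+p) ≈ 0.90 at p = 0.05 independent of prototype density, against
  between-cluster similarity at the prototype-overlap level (~0.02). The
  deletion model mimics a family of analogues sharing a scaffold whose
  members each lack a few substructure keys; it does not model additive
  decorations, ring rearrangements or the key-correlation structure of
  real MACCS fingerprints, so recovery results bound what clean,
  well-separated chemical families would show, not pathological libraries.
* **Gene fixtures** plant exact per-molecule overlap counts with a disease
  set (decoy targets come from a disjoint token pool), so ranking tests
  have construction-level ground truth. Symbols are synthetic tokens.
* **Networks** realize a requested hub degree sequence (Havel–Hakimi, then
  degree-preserving edge swaps for randomness; a swap annealer stalling on
  rigid graphs such as stars is tolerated). Filler degrees must stay below
  the smallest hub degree; an odd handshake sum is fixed by lowering one
  filler's degree by one.
* **MM/PBSA snapshots** are independent Gaussians per component. Real
  trajectories correlate ΔE_ele and ΔG_solv (electrostatic solvation
  compensation), so the synthetic ΔG_total spread overstates a real one at
  equal component spreads; tests therefore check mean recovery at
  3σ/√n, not spread.
* **Hydrogen-bond frames** are count-exact: a pair with occupancy q% is
  planted in exactly round(q·n/100) frames, making recomputed occupancies
  deterministic rather than Bernoulli-noisy.

All generators are bit-reproducible per seed, and each one's ground truth
is recovered exactly by its analysis operation in the noiseless limit.

## Problem sizes

The test suite and the reproduction script use the generators' default
conditions: 120-molecule planted libraries for clustering recovery,
20-snapshot energy tables, 1000-frame hydrogen-bond sets, oracle-equivalence
batches of ≤ 40 points (hierarchical clustering), ≤ 50 nodes (degree
ranking) and universes ≤ 12 genes (exhaustive hypergeometric enumeration).
These sizes match the motivating screen's own scales (139 compounds, 20
MM/PBSA snapshots, 1000 trajectory frames) while keeping exhaustive oracles
exact.

## Known limitations

* No docking, molecular dynamics, or PB/GB solvers are included or wrapped;
  the energetics module starts from their tabulated outputs.
* The 139-compound thunder-god-vine library is not redistributed here (no
  public machine-readable deposit exists); clustering claims are validated
  on planted libraries and small hand-written SMILES sets.
* Gene identifiers are treated as opaque tokens — no alias mapping, no
  live STRING/GeneMANIA/UniProt queries, no bundled GO/KEGG databases;
  annotation sets are supplied as GMT files.
* t-SNE determinism is guaranteed per (input, config, seed) triple, not
  across library versions of the underlying optimizer.
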