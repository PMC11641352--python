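"""Three-dimensional chemical-space embedding and hierarchical clustering.

This is the "3DH" half of the clustering/representative-selection chain:
binary fingerprints are embedded into three dimensions with t-SNE (on the
Jaccard distance 1 − Tanimoto by default), the embedded points are
agglomeratively clustered, and the dendrogram is cut into k groups.

t-SNE follows the standard formulation: per-point Gaussian bandwidths are
calibrated so the conditional-distribution entropy matches log(perplexity),
affinities are symmetrized, the low-dimensional kernel is Student-t with one
degree of freedom, and the KL divergence is minimized by momentum gradient
descent with an early-exaggeration phase.  scikit-learn's exact-method
implementation provides this contract; the seed makes runs bit-reproducible.

Agglomeration is implemented directly (Lance–Williams updates on the full
distance matrix) so that merge order and tie-breaking are fully specified:
among equally close pairs the one with the smallest (left, right) cluster
creation index is merged first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.manifold import TSNE

from .errors import ClusteringError
from .fingerprints import Fingerprint, SimilarityMatrix, jaccard_distance_matrix

logger = logging.getLogger(__name__)

LINKAGES = ("single", "complete", "average", "ward")
METRICS = ("jaccard_distance", "euclidean_on_bits")

#: Additive jitter applied to zero off-diagonal distances (duplicate
#: molecules) so bandwidth calibration never divides by zero.
ZERO_DISTANCE_JITTER = 1e-10


@dataclass(frozen=True)
class EmbeddingConfig:
    """t-SNE hyperparameters.

    perplexity
        Effective number of neighbors; capped at run time to (n−1)/3.
    iterations
        Gradient-descent iterations (including the early-exaggeration phase).
    learning_rate
        Step size for the momentum optimizer.  The default ``"auto"`` uses
        n / early_exaggeration (floored at 1), the adaptive rule that keeps
        the exaggeration-phase update magnitude independent of sample size;
        fixed rates tuned for large embeddings diverge on small libraries
        with unit-scale Jaccard distances.
    early_exaggeration
        Affinity multiplier for the first phase of the optimization.
    seed
        Mandatory; fixes the random initialization.
    metric
        ``jaccard_distance`` (1 − Tanimoto on fingerprints, default) or
        ``euclidean_on_bits`` (Euclidean distance between raw bit vectors).
    """

    seed: int
    perplexity: float = 30.0
    iterations: int = 1000
    learning_rate: float | str = "auto"
    early_exaggeration: float = 12.0
    metric: str = "jaccard_distance"

    def __post_init__(self):
        if self.perplexity <= 0 or self.iterations <= 0:
            raise ClusteringError("perplexity and iterations must be positive")
        if self.learning_rate != "auto" and not self.learning_rate > 0:
            raise ClusteringError("learning_rate must be positive or 'auto'")
        if self.early_exaggeration <= 0:
            raise ClusteringError("early_exaggeration must be positive")
        if self.metric not in METRICS:
            raise ClusteringError(f"unknown metric {self.metric!r}; choose from {METRICS}")


@dataclass(frozen=True)
class Embedding3D:
    """n molecules embedded as n×3 real coordinates."""

    ids: tuple[str, ...]
    coords: np.ndarray = field(repr=False)
    config: EmbeddingConfig | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ClusteringError(f"embedding must be n×3, got {coords.shape}")
        if coords.shape[0] != len(self.ids):
            raise ClusteringError("ids and coordinate rows differ in length")
        if not np.all(np.isfinite(coords)):
            raise ClusteringError("non-finite embedding coordinates")


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history: (left, right, height, size) per merge.

    Leaves are numbered 0..n−1 in input order; the i-th merge creates
    cluster n+i.  ``left < right`` in every row.
    """

    n_leaves: int
    merges: tuple[tuple[int, int, float, int], ...]
    linkage: str
    ids: tuple[str, ...] | None = None

    def __post_init__(self):
        if len(self.merges) != self.n_leaves - 1:
            raise ClusteringError(
                f"{self.n_leaves} leaves require {self.n_leaves - 1} merges, "
                f"got {len(self.merges)}"
            )

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def to_linkage_matrix(self) -> np.ndarray:
        """SciPy-format linkage matrix (for dendrogram plots, fcluster, ...)."""
        return np.array([[l, r, h, s] for l, r, h, s in self.merges], dtype=float)

    def to_newick(self) -> str:
        """Newick string with merge heights as node heights.

        Branch lengths are the height differences between a node and its
        parent merge, so leaf-to-root path lengths equal the root height.
        """
        labels = list(self.ids) if self.ids else [str(i) for i in range(self.n_leaves)]
        height = {i: 0.0 for i in range(self.n_leaves)}
        text = {i: labels[i] for i in range(self.n_leaves)}
        for t, (left, right, h, _size) in enumerate(self.merges):
            node = self.n_leaves + t
            parts = []
            for child in (left, right):
                parts.append(f"{text[child]}:{h - height[child]:.10g}")
            text[node] = f"({parts[0]},{parts[1]})"
            height[node] = h
        root = self.n_leaves + len(self.merges) - 1
        return text[root] + ";"


@dataclass(frozen=True)
class ClusterAssignment:
    """Molecule id → cluster index in 1..k; every cluster non-empty."""

    labels: dict[str, int]
    k: int

    def __post_init__(self):
        found = set(self.labels.values())
        if found != set(range(1, self.k + 1)):
            raise ClusteringError(
                f"labels must cover clusters 1..{self.k} with none empty, got {sorted(found)}"
            )

    def members(self, cluster: int) -> list[str]:
        return [mid for mid, c in self.labels.items() if c == cluster]


def _distance_matrix(
    data: SimilarityMatrix | list[Fingerprint], metric: str
) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(data, SimilarityMatrix):
        return 1.0 - data.values, data.ids
    if metric == "jaccard_distance":
        return jaccard_distance_matrix(data), None
    bits = np.stack([fp.bits for fp in data]).astype(float)
    diff = bits[:, None, :] - bits[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1)), None


def tsne_embed(
    data: SimilarityMatrix | list[Fingerprint],
    config: EmbeddingConfig,
    ids: list[str] | None = None,
) -> Embedding3D:
    """Embed fingerprints (or a precomputed similarity matrix) into 3-D.

    Deterministic for a given input and config (including seed).  The
    perplexity is capped to (n−1)/3 if infeasible for the library size;
    zero pairwise distances between duplicate molecules receive a tiny
    additive jitter before bandwidth calibration.
    """
    dist, matrix_ids = _distance_matrix(data, config.metric)
    n = dist.shape[0]
    if n < 4:
        raise ClusteringError(f"t-SNE needs at least 4 molecules, got {n}")
    if ids is None:
        ids = list(matrix_ids) if matrix_ids else [f"M{i}" for i in range(n)]

    max_perplexity = (n - 1) / 3
    perplexity = config.perplexity
    if perplexity >= max_perplexity:
        perplexity = max(1.0, np.nextafter(max_perplexity, 0.0))
        logger.info("perplexity capped to %.3f for n=%d", perplexity, n)
        config = replace(config, perplexity=perplexity)

    off_diag = ~np.eye(n, dtype=bool)
    if np.any(dist[off_diag] == 0.0):
        dist = dist.copy()
        dist[off_diag & (dist == 0.0)] = ZERO_DISTANCE_JITTER

    learning_rate = config.learning_rate
    if learning_rate == "auto":
        learning_rate = max(n / config.early_exaggeration, 1.0)

    logger.info(
        "t-SNE: n=%d perplexity=%.2f iterations=%d lr=%.1f seed=%d metric=%s",
        n, perplexity, config.iterations, learning_rate, config.seed, config.metric,
    )
    tsne = TSNE(
        n_components=3,
        metric="precomputed",
        method="exact",
        init="random",
        perplexity=perplexity,
        max_iter=config.iterations,
        learning_rate=learning_rate,
        early_exaggeration=config.early_exaggeration,
        random_state=config.seed,
    )
    # sklearn's exact method squares the precomputed matrix in place
    coords = tsne.fit_transform(dist.copy())
    if not np.all(np.isfinite(coords)):
        raise ClusteringError("t-SNE produced non-finite coordinates")
    return Embedding3D(ids=tuple(ids), coords=coords, config=config)


def _lance_williams(linkage: str, d_ki: float, d_kj: float, d_ij: float,
                    nk: int, ni: int, nj: int) -> float:
    if linkage == "single":
        return min(d_ki, d_kj)
    if linkage == "complete":
        return max(d_ki, d_kj)
    if linkage == "average":
        return (ni * d_ki + nj * d_kj) / (ni + nj)
    # ward on Euclidean distances
    total = nk + ni + nj
    sq = ((nk + ni) * d_ki**2 + (nk + nj) * d_kj**2 - nk * d_ij**2) / total
    return float(np.sqrt(max(sq, 0.0)))


def agglomerate(points: Embedding3D | np.ndarray, linkage: str = "ward",
                ids: list[str] | None = None) -> Dendrogram:
    """Agglomeratively cluster embedded points into a full dendrogram.

    Repeatedly merges the closest pair of clusters under the chosen linkage
    (single, complete, average or ward, on Euclidean distances).  Ties are
    broken by the smallest (left, right) cluster creation index, so the
    merge history is deterministic.
    """
    if linkage not in LINKAGES:
        raise ClusteringError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if isinstance(points, Embedding3D):
        coords = points.coords
        ids = list(points.ids)
    else:
        coords = np.asarray(points, dtype=float)
        if coords.ndim == 1:
            coords = coords[:, None]
    n = coords.shape[0]
    if n < 2:
        raise ClusteringError(f"clustering needs at least 2 points, got {n}")

    # for singletons the ward inter-cluster distance sqrt(2ninj/(ni+nj))·‖ci−cj‖
    # reduces to the plain Euclidean distance, so one seed matrix serves all linkages
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))

    # active clusters keyed by creation index
    dmat: dict[tuple[int, int], float] = {}
    active: list[int] = list(range(n))
    size = {i: 1 for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            dmat[(i, j)] = float(dist[i, j])

    merges: list[tuple[int, int, float, int]] = []
    next_idx = n
    while len(active) > 1:
        best = None
        for a_pos in range(len(active)):
            for b_pos in range(a_pos + 1, len(active)):
                i, j = active[a_pos], active[b_pos]
                d = dmat[(i, j)]
                if best is None or d < best[0] or (d == best[0] and (i, j) < best[1:]):
                    best = (d, i, j)
        d, i, j = best
        merges.append((i, j, d, size[i] + size[j]))
        new = next_idx
        next_idx += 1
        size[new] = size[i] + size[j]
        active.remove(i)
        active.remove(j)
        for k in active:
            d_ki = dmat[tuple(sorted((k, i)))]
            d_kj = dmat[tuple(sorted((k, j)))]
            dmat[(min(k, new), max(k, new))] = _lance_williams(
                linkage, d_ki, d_kj, d, size[k], size[i], size[j]
            )
        active.append(new)

    return Dendrogram(
        n_leaves=n,
        merges=tuple(merges),
        linkage=linkage,
        ids=tuple(ids) if ids else None,
    )


def cut_to_k(dendro: Dendrogram, k: int) -> ClusterAssignment:
    """Cut a dendrogram into exactly k clusters by undoing the last k−1 merges.

    Clusters are numbered 1..k in order of their smallest leaf index.
    """
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise ClusteringError(f"k must be in 1..{n}, got {k}")
    parent = list(range(n + len(dendro.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (left, right, _h, _s) in enumerate(dendro.merges[: n - k]):
        node = n + t
        parent[find(left)] = node
        parent[find(right)] = node

    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    groups = sorted(roots.values(), key=lambda leaves: leaves[0])
    assert len(groups) == k

    ids = list(dendro.ids) if dendro.ids else [str(i) for i in range(n)]
    labels = {ids[leaf]: c for c, leaves in enumerate(groups, start=1) for leaf in leaves}
    return ClusterAssignment(labels=labels, k=k)


def cluster_fingerprints(
    fps: list[Fingerprint],
    ids: list[str],
    config: EmbeddingConfig,
    k: int = 6,
    linkage: str = "ward",
) -> tuple[ClusterAssignment, Embedding3D]:
    """Embed fingerprints into 3-D, agglomerate, and cut into k clusters."""
    embedding = tsne_embed(fps, config, ids=ids)
    dendro = agglomerate(embedding, linkage=linkage)
    assignment = cut_to_k(dendro, k)
    logger.info("clustered %d molecules into %d groups (%s linkage)", len(fps), k, linkage)
    return assignment, embedding


def cluster_pipeline(
    library,
    scheme: str = "maccs",
    config: EmbeddingConfig | None = None,
    k: int = 6,
    linkage: str = "ward",
) -> tuple[ClusterAssignment, Embedding3D]:
    """Full chain on a parsed compound library: fingerprint → embed → cluster.

    ``library`` is a list of :class:`~tgvscreen.fingerprints.Molecule`.
    """
    from .fingerprints import compute_fingerprint

    if config is None:
        config = EmbeddingConfig(seed=0)
    fps = [compute_fingerprint(mol, scheme) for mol in library]
    ids = [mol.id for mol in library]
    logger.info("fingerprinted %d molecules with scheme %s", len(fps), scheme)
    return cluster_fingerprints(fps, ids, config, k=k, linkage=linkage)
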