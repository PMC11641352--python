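"""Tanimoto medoid representative selection — the "TRS" half of the chain.

Each cluster's representative is its medoid under Tanimoto similarity: the
member with the highest arithmetic-mean similarity to the other members of
the same cluster (self excluded).  A singleton cluster represents itself
with mean similarity defined as 1.0.  Ties go to the lexicographically
smallest molecule id.
"""

from __future__ import annotations

from dataclasses import dataclass

from .embed_cluster import ClusterAssignment
from .errors import ClusteringError
from .fingerprints import Fingerprint, similarity_matrix


@dataclass(frozen=True)
class ClusterRepresentative:
    cluster: int
    molecule_id: str
    mean_similarity: float


def select_representative(
    fps: list[Fingerprint], ids: list[str], cluster: int = 1
) -> ClusterRepresentative:
    """Pick the Tanimoto medoid of one cluster's members."""
    if not fps:
        raise ClusteringError("cannot select a representative from an empty cluster")
    if len(fps) != len(ids):
        raise ClusteringError("ids and fingerprints differ in length")
    if len(fps) == 1:
        return ClusterRepresentative(cluster=cluster, molecule_id=ids[0], mean_similarity=1.0)

    sim = similarity_matrix(fps, ids).values
    m = len(fps)
    mean_sim = (sim.sum(axis=1) - 1.0) / (m - 1)  # drop the unit self-similarity
    best = min(range(m), key=lambda i: (-mean_sim[i], ids[i]))
    return ClusterRepresentative(
        cluster=cluster, molecule_id=ids[best], mean_similarity=float(mean_sim[best])
    )


def select_all(
    assignment: ClusterAssignment, fps: dict[str, Fingerprint]
) -> list[ClusterRepresentative]:
    """One representative per cluster, in cluster order; deterministic."""
    missing = [mid for mid in assignment.labels if mid not in fps]
    if missing:
        raise ClusteringError(f"missing fingerprints for: {', '.join(sorted(missing))}")
    reps = []
    for cluster in range(1, assignment.k + 1):
        members = sorted(assignment.members(cluster))
        reps.append(
            select_representative([fps[m] for m in members], members, cluster=cluster)
        )
    return reps
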