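"""Synthetic fixtures with known ground truth for every pipeline stage.

Each generator emulates one input the toolkit consumes — clustered binary
fingerprint libraries, compound-target/disease-gene tables with planted
overlap counts, hub-structured interaction networks, Gaussian MM/PBSA
snapshot tables and frame-wise hydrogen-bond records — and is
bit-reproducible per seed.  In the noiseless limit (flip probability 0,
standard deviation 0, count-exact occupancies) the corresponding analysis
operation recovers the planted ground truth exactly.

Gene symbols are synthetic tokens (G0001, …); no real gene semantics are
implied.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .energetics import HBondFrame
from .errors import SyntheticSpecError
from .fingerprints import Fingerprint
from .netpharm import GeneSet

#: Probability that a prototype sets one of its own preferred bits / a
#: stray bit from another cluster's block.  Chosen so prototypes are
#: dense enough for stable Tanimoto values yet share well under 10% of
#: their set bits, keeping within-cluster similarity far above
#: between-cluster similarity.
_PREFERRED_ON = 0.6
_STRAY_ON = 0.02


@dataclass(frozen=True)
class PlantedLibrary:
    """A fingerprint library with planted cluster structure."""

    ids: tuple[str, ...]
    fingerprints: tuple[Fingerprint, ...]
    true_labels: dict[str, int]
    params: dict

    def __len__(self) -> int:
        return len(self.ids)


def gen_fingerprint_library(
    k: int = 6,
    m: int = 20,
    bits: int = 166,
    flip_prob: float = 0.05,
    seed: int = 0,
) -> PlantedLibrary:
    """Generate k clusters of m noisy copies of disjoint-biased prototypes.

    Each cluster owns a contiguous block of ~bits/k preferred positions;
    its prototype turns each preferred bit on with high probability and
    each foreign bit on with low probability, so prototypes are nearly
    disjoint.  Every member then flips each of its prototype's set bits
    off independently with ``flip_prob`` (deletion noise), which makes the
    expected within-cluster Tanimoto (1−p)/(1+p) regardless of prototype
    density — ≈0.90 at p = 0.05 — while between-cluster similarity stays
    at the prototype-overlap level.  All-zero members are redrawn.
    """
    if k < 1 or m < 1 or bits < k:
        raise SyntheticSpecError(f"need k,m ≥ 1 and bits ≥ k, got k={k} m={m} bits={bits}")
    if bits not in (166, 2048):
        raise SyntheticSpecError("bit length must be 166 (maccs) or 2048 (hashed)")
    if not 0 <= flip_prob < 0.5:
        raise SyntheticSpecError(f"flip_prob must be in [0, 0.5), got {flip_prob}")
    scheme = "maccs" if bits == 166 else "hashed"
    rng = np.random.default_rng(seed)

    block = np.array_split(np.arange(bits), k)
    prototypes = []
    for c in range(k):
        proto = rng.random(bits) < _STRAY_ON
        proto[block[c]] = rng.random(len(block[c])) < _PREFERRED_ON
        if not proto.any():
            proto[block[c][0]] = True
        prototypes.append(proto)

    ids, fps, labels = [], [], {}
    width = len(str(k * m))
    idx = 0
    for c, proto in enumerate(prototypes, start=1):
        for _ in range(m):
            while True:
                drop = (rng.random(bits) < flip_prob) & proto
                member = proto & ~drop
                if member.any():
                    break
            idx += 1
            mol_id = f"M{idx:0{width}d}"
            ids.append(mol_id)
            fps.append(Fingerprint(bits=member, scheme=scheme))
            labels[mol_id] = c
    return PlantedLibrary(
        ids=tuple(ids),
        fingerprints=tuple(fps),
        true_labels=labels,
        params={"k": k, "m": m, "bits": bits, "flip_prob": flip_prob, "seed": seed},
    )


def gen_gene_fixtures(
    n_molecules: int,
    n_disease: int,
    overlap_spec: dict[str, int],
    seed: int = 0,
    n_offtarget: int = 5,
) -> tuple[dict[str, GeneSet], GeneSet]:
    """Build a target map whose per-molecule disease overlap is exact.

    Each molecule in ``overlap_spec`` receives exactly that many genes from
    the disease set plus ``n_offtarget`` decoys drawn from a disjoint pool,
    so ``overlap`` reproduces the requested counts by construction.
    Molecules absent from ``overlap_spec`` get only decoys.
    """
    if n_molecules < 1 or n_disease < 1:
        raise SyntheticSpecError("need at least one molecule and one disease gene")
    bad = {m: c for m, c in overlap_spec.items() if c < 0 or c > n_disease}
    if bad:
        raise SyntheticSpecError(f"infeasible overlap counts (0..{n_disease}): {bad}")
    if len(overlap_spec) > n_molecules:
        raise SyntheticSpecError("overlap_spec lists more molecules than n_molecules")
    rng = np.random.default_rng(seed)
    disease_genes = [f"G{i:04d}" for i in range(1, n_disease + 1)]
    decoy_pool = [f"D{i:04d}" for i in range(1, 10 * n_offtarget + n_molecules + 1)]
    disease = GeneSet(label="disease", genes=frozenset(disease_genes))

    mol_ids = sorted(overlap_spec)
    pad = 1
    while len(mol_ids) < n_molecules:
        candidate = f"MOL{pad:03d}"
        pad += 1
        if candidate not in overlap_spec:
            mol_ids.append(candidate)

    tmap: dict[str, GeneSet] = {}
    for mol in mol_ids:
        count = overlap_spec.get(mol, 0)
        hits = rng.choice(disease_genes, size=count, replace=False).tolist() if count else []
        decoys = rng.choice(decoy_pool, size=n_offtarget, replace=False).tolist()
        tmap[mol] = GeneSet(label=mol, genes=frozenset(hits + decoys))
    return tmap, disease


def gen_network(
    n_nodes: int,
    hub_spec: list[tuple[str, int]],
    seed: int = 0,
    filler_degree: int = 2,
) -> nx.Graph:
    """Build a PPI-like graph whose top-degree nodes are exactly ``hub_spec``.

    ``hub_spec`` lists (symbol, degree) pairs in the order degree ranking
    must return them (degrees non-increasing; equal-degree hubs must be in
    symbol order).  Filler nodes get ``filler_degree``, which must be below
    the smallest hub degree.  The degree sequence must be graphical.
    """
    if n_nodes < len(hub_spec) + 1:
        raise SyntheticSpecError("n_nodes must exceed the number of hubs")
    degrees = [d for _s, d in hub_spec]
    if any(d < 1 for d in degrees):
        raise SyntheticSpecError("hub degrees must be ≥ 1")
    for (s1, d1), (s2, d2) in zip(hub_spec, hub_spec[1:]):
        if d1 < d2 or (d1 == d2 and s1 >= s2):
            raise SyntheticSpecError(
                "hub_spec must be sorted by degree descending, ties by symbol ascending"
            )
    if degrees and filler_degree >= degrees[-1]:
        raise SyntheticSpecError(
            f"filler degree {filler_degree} must be below the smallest hub degree {degrees[-1]}"
        )
    n_filler = n_nodes - len(hub_spec)
    sequence = degrees + [filler_degree] * n_filler
    if sum(sequence) % 2 == 1:
        # drop one filler's degree by one so the handshake sum is even
        sequence[-1] = filler_degree - 1
    if not nx.is_graphical(sequence):
        raise SyntheticSpecError(f"degree sequence {sequence} is not graphical")

    graph = nx.havel_hakimi_graph(sequence)
    # havel_hakimi nodes are indexed in sequence order: hubs first, fillers after
    symbols = [s for s, _d in hub_spec] + [f"N{i:04d}" for i in range(1, n_filler + 1)]
    graph = nx.relabel_nodes(graph, dict(enumerate(symbols)))
    # randomize wiring while preserving every degree; degree-constrained graphs
    # (e.g. stars) may admit few swaps, so a stalled annealer is not an error
    n_edges = graph.number_of_edges()
    if n_edges > 1:
        try:
            nx.double_edge_swap(graph, nswap=2 * n_edges, max_tries=100 * n_edges, seed=seed)
        except nx.NetworkXAlgorithmError:
            pass
    return graph


def gen_mmpbsa_snapshots(
    means: dict[str, float],
    stds: dict[str, float],
    n: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian per-snapshot MM/PBSA component samples (kcal/mol).

    ``means``/``stds`` give the population mean and spread of ``evdw``,
    ``eele`` and ``gsolv``; n snapshots are drawn independently per column.
    """
    required = ("evdw", "eele", "gsolv")
    missing = [c for c in required if c not in means or c not in stds]
    if missing:
        raise SyntheticSpecError(f"means/stds must define {', '.join(missing)}")
    if n < 1:
        raise SyntheticSpecError(f"need n ≥ 1 snapshots, got {n}")
    if any(stds[c] < 0 for c in required):
        raise SyntheticSpecError("standard deviations must be ≥ 0")
    rng = np.random.default_rng(seed)
    data = {"snapshot": np.arange(1, n + 1)}
    for col in required:
        data[col] = rng.normal(means[col], stds[col], size=n)
    return pd.DataFrame(data)


def gen_hbond_frames(
    occupancy_map: dict[tuple[str, str], float],
    n_frames: int = 1000,
    seed: int = 0,
) -> list[HBondFrame]:
    """Frame-wise hydrogen-bond records hitting each occupancy exactly.

    For a pair with occupancy p%, the pair is present in exactly
    round(p·n/100) frames (chosen at random), so recomputed occupancies are
    deterministic rather than Bernoulli-noisy.
    """
    if n_frames < 1:
        raise SyntheticSpecError(f"need n_frames ≥ 1, got {n_frames}")
    for pair, occ in occupancy_map.items():
        if not 0 <= occ <= 100:
            raise SyntheticSpecError(f"occupancy for {pair} must be in [0, 100], got {occ}")
    rng = np.random.default_rng(seed)
    bonds_by_frame: dict[int, list[tuple[str, str]]] = {i: [] for i in range(n_frames)}
    for pair, occ in sorted(occupancy_map.items()):
        count = int(round(occ * n_frames / 100.0))
        for idx in rng.choice(n_frames, size=count, replace=False):
            bonds_by_frame[int(idx)].append(pair)
    return [HBondFrame(frame=i, bonds=tuple(b)) for i, b in sorted(bonds_by_frame.items())]


def write_hbond_frames(frames: list[HBondFrame], path) -> None:
    """Write frames as a (frame,donor,acceptor) CSV; bond-free frames keep a
    row with empty donor/acceptor so the frame count survives a round trip."""
    rows = []
    for fr in frames:
        if fr.bonds:
            rows.extend({"frame": fr.frame, "donor": d, "acceptor": a} for d, a in fr.bonds)
        else:
            rows.append({"frame": fr.frame, "donor": "", "acceptor": ""})
    pd.DataFrame(rows, columns=["frame", "donor", "acceptor"]).to_csv(path, index=False)
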