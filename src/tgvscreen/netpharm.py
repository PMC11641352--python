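"""Network-pharmacology arithmetic: gene-set merging, target intersection,
molecule ranking, hub-gene ranking and hypergeometric enrichment.

Gene symbols are treated as plain case-normalized tokens (upper-cased,
whitespace-trimmed); no alias resolution is attempted.  Disease-gene source
lists may carry relevance scores, which are filtered with a strict
``score > threshold`` rule before the union (unscored records are always
kept).  Hubness is plain degree centrality on the undirected
protein–protein interaction graph.  Enrichment is the one-sided
(upper-tail) hypergeometric test with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import GeneSetError


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A labeled set of case-normalized gene symbols."""

    label: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, label: str, genes) -> "GeneSet":
        normalized = {normalize_symbol(g) for g in genes if str(g).strip()}
        return cls(label=label, genes=frozenset(normalized))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.genes


@dataclass(frozen=True)
class ScoredGeneList:
    """A source list of (gene symbol, optional relevance score) records."""

    source: str
    records: tuple[tuple[str, float | None], ...]

    def __post_init__(self):
        for symbol, score in self.records:
            if score is not None and not math.isfinite(score):
                raise GeneSetError(f"{self.source}: non-finite score for {symbol!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap: int
    term_size: int
    query_size: int
    universe_size: int
    p_value: float
    p_adjusted: float
    genes: frozenset[str] = field(default_factory=frozenset)


def merge_disease_genes(
    lists: list[ScoredGeneList], threshold: float = 5.0, inclusive: bool = False
) -> GeneSet:
    """Union of disease-gene source lists after relevance filtering.

    A scored record survives only if its score exceeds ``threshold``
    (strictly, by default; set ``inclusive`` for ≥).  Unscored records are
    always kept.  The result is deduplicated and case-normalized.
    """
    if not lists:
        raise GeneSetError("at least one source list is required")
    kept: set[str] = set()
    for source in lists:
        for symbol, score in source.records:
            if score is None or score > threshold or (inclusive and score >= threshold):
                kept.add(normalize_symbol(symbol))
    kept.discard("")
    if not kept:
        raise GeneSetError("merged disease-gene set is empty after filtering")
    return GeneSet(label="+".join(s.source for s in lists), genes=frozenset(kept))


def overlap(targets: GeneSet, disease: GeneSet) -> tuple[GeneSet, int]:
    """Intersection of a compound's predicted targets with the disease set."""
    inter = targets.genes & disease.genes
    return GeneSet(label=f"{targets.label}∩{disease.label}", genes=frozenset(inter)), len(inter)


def rank_molecules(
    tmap: dict[str, GeneSet], disease: GeneSet, top: int = 6
) -> list[tuple[str, int]]:
    """Rank molecules by the size of their target ∩ disease-gene overlap.

    Descending by count; ties broken by molecule id ascending; truncated to
    ``top``.
    """
    if not tmap:
        raise GeneSetError("empty target map")
    if top < 1:
        raise GeneSetError(f"top must be ≥ 1, got {top}")
    counts = [(mol, overlap(targets, disease)[1]) for mol, targets in tmap.items()]
    counts.sort(key=lambda rec: (-rec[1], rec[0]))
    return counts[:top]


def top_hubs(network: nx.Graph, n: int = 10) -> list[tuple[str, int]]:
    """Top-n hub genes of a PPI network by degree.

    Sorted by degree descending, ties by symbol ascending; returns fewer
    than n entries if the network is smaller.
    """
    if network.number_of_nodes() == 0:
        raise GeneSetError("empty interaction network")
    if n < 1:
        raise GeneSetError(f"n must be ≥ 1, got {n}")
    degrees = sorted(network.degree(), key=lambda rec: (-rec[1], rec[0]))
    return [(str(g), int(d)) for g, d in degrees[:n]]


def hypergeom_enrich(
    query: GeneSet,
    annotations: dict[str, set[str] | frozenset[str]],
    universe: GeneSet,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a gene set against GMT terms.

    For each term with K annotated genes in a universe of N, the p-value is
    P(X ≥ k) for the overlap k of an n-gene query; p-values are
    Benjamini–Hochberg adjusted across all terms.  Annotation sets are
    intersected with the universe first; the query must be a subset of the
    universe.  Results are sorted by adjusted then raw p-value.
    """
    stray = query.genes - universe.genes
    if stray:
        raise GeneSetError(f"query genes outside the universe: {', '.join(sorted(stray))}")
    big_n = len(universe.genes)
    n = len(query.genes)
    terms, pvals, rows = [], [], []
    for term, members in annotations.items():
        members = {normalize_symbol(g) for g in members} & universe.genes
        hit = query.genes & members
        k, big_k = len(hit), len(members)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n)) if k > 0 else 1.0
        terms.append(term)
        pvals.append(min(p, 1.0))
        rows.append((term, k, big_k, hit))
    if not terms:
        return []
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term=term, overlap=k, term_size=big_k, query_size=n,
            universe_size=big_n, p_value=p, p_adjusted=float(q), genes=frozenset(hit),
        )
        for (term, k, big_k, hit), p, q in zip(rows, pvals, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_value, r.term))
    return results


def merge_neighbor_lists(hubs: GeneSet, neighbor_lists: list[GeneSet]) -> GeneSet:
    """Deduplicated union of hub genes and their network-neighbor lists.

    The list-union arithmetic behind building an expanded disease-gene
    database from hub genes plus the genes each hub pulls in from a
    functional-association network.
    """
    union = set(hubs.genes)
    for gs in neighbor_lists:
        union |= gs.genes
    return GeneSet(label=f"{hubs.label}+neighbors", genes=frozenset(union))


# --- file formats -----------------------------------------------------------

def read_gene_list(path: str | Path, source: str | None = None) -> ScoredGeneList:
    """Read a TSV of ``symbol[<tab>score]`` records (no header, '#' comments)."""
    path = Path(path)
    records: list[tuple[str, float | None]] = []
    with path.open() as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            score = float(fields[1]) if len(fields) > 1 else None
            records.append((fields[0], score))
    return ScoredGeneList(source=source or path.stem, records=tuple(records))


def read_target_map(path: str | Path) -> dict[str, GeneSet]:
    """Read a two-column TSV of (molecule_id, gene symbol) pairs."""
    df = pd.read_csv(path, sep="\t", header=None, names=["molecule", "symbol"], comment="#")
    tmap: dict[str, set[str]] = {}
    for mol, sym in zip(df["molecule"], df["symbol"]):
        tmap.setdefault(str(mol), set()).add(normalize_symbol(str(sym)))
    return {mol: GeneSet(label=mol, genes=frozenset(genes)) for mol, genes in tmap.items()}


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected PPI edge list (two tab-separated symbols per line).

    Self-loops are dropped and duplicate edges collapse.
    """
    graph = nx.Graph()
    with Path(path).open() as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise GeneSetError(f"malformed edge line: {line!r}")
            a, b = normalize_symbol(fields[0]), normalize_symbol(fields[1])
            if a != b:
                graph.add_edge(a, b)
    return graph


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read gene sets from a GMT file (name, description, members…)."""
    sets: dict[str, frozenset[str]] = {}
    with Path(path).open() as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetError(f"GMT line needs name, description, ≥1 gene: {line!r}")
            sets[fields[0]] = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
    return sets


def gmt_universe(annotations: dict[str, set[str] | frozenset[str]]) -> GeneSet:
    """Default enrichment universe: every gene appearing in the GMT file."""
    union: set[str] = set()
    for members in annotations.values():
        union |= {normalize_symbol(g) for g in members}
    return GeneSet(label="gmt-universe", genes=frozenset(union))
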