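"""Disease-network construction and topology-based node ranking.

The disease network is the graph whose nodes are the genes shared between
the measured transcriptome and a curated disease reference gene list, and
whose edges are PPI links above a confidence threshold.  Genes left without
a single qualifying edge are dropped: network analysis has nothing to say
about an isolated node, and this is what reconciles a shared-gene set that
is larger than the final node count.

The NTRA score implemented here — z(|disease log2FC|) + z(log(degree+1)) —
is a declared stand-in combining transcriptomic perturbation with topological
centrality; the originally published ranking is not specified by a formula
anywhere we can reimplement from, so this heuristic should be treated as a
documented placeholder, not the published method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "ReferenceGeneSet",
    "DiseaseNetwork",
    "NetworkBuildError",
    "normalize_gene_id",
    "intersect_universe",
    "build_network",
    "ntra_rank",
]


class NetworkBuildError(ValueError):
    """Raised when no usable network can be built from the inputs."""


def normalize_gene_id(gene: str) -> str:
    """Canonical gene id: whitespace-stripped, uppercased. No alias mapping."""
    return str(gene).strip().upper()


@dataclass(frozen=True)
class ReferenceGeneSet:
    """A curated disease gene list (e.g. a CVD gene database export)."""

    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self):
        norm = [normalize_gene_id(g) for g in self.genes]
        if len(set(norm)) != len(norm):
            raise ValueError("reference gene list contains duplicates after case-normalization")
        object.__setattr__(self, "genes", tuple(norm))

    def __len__(self) -> int:
        return len(self.genes)


def intersect_universe(transcriptome_genes: Iterable[str],
                       reference: ReferenceGeneSet | Iterable[str]) -> list[str]:
    """Genes shared between the measured transcriptome and the disease reference list.

    Matching is exact after case-normalization; the result is deduplicated
    and sorted for determinism.  An empty intersection warns and returns [].
    """
    universe = {normalize_gene_id(g) for g in transcriptome_genes}
    ref = reference.genes if isinstance(reference, ReferenceGeneSet) else reference
    ref_set = {normalize_gene_id(g) for g in ref}
    if not universe or not ref_set:
        raise ValueError("both gene lists must be non-empty")
    shared = sorted(universe & ref_set)
    if not shared:
        warnings.warn("transcriptome and reference gene lists share no genes")
    return shared


@dataclass
class DiseaseNetwork:
    """Gene graph with per-node disease statistics and topology attributes.

    Node attributes (filled progressively): ``degree`` always;
    ``disease_log2fc``, ``ntra_score`` and ``ntra_rank`` after
    :func:`ntra_rank`.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self):
        if any(self.graph.has_edge(v, v) for v in self.graph):
            raise ValueError("disease network must not contain self-loops")
        nx.set_node_attributes(self.graph, dict(self.graph.degree()), "degree")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes())

    def node_table(self) -> pd.DataFrame:
        """Per-node attribute table, sorted by gene id."""
        rows = []
        for g in self.nodes:
            attrs = self.graph.nodes[g]
            rows.append({
                "gene": g,
                "degree": attrs.get("degree", self.graph.degree(g)),
                "disease_log2fc": attrs.get("disease_log2fc", np.nan),
                "ntra_score": attrs.get("ntra_score", np.nan),
                "ntra_rank": attrs.get("ntra_rank", np.nan),
            })
        return pd.DataFrame(rows).set_index("gene")

    def edge_table(self) -> pd.DataFrame:
        rows = [(min(a, b), max(a, b), d.get("confidence", np.nan))
                for a, b, d in self.graph.edges(data=True)]
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def to_edge_tsv(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)


def build_network(gene_set: Iterable[str], edges: pd.DataFrame,
                  min_confidence: float = 0.4) -> DiseaseNetwork:
    """Assemble the disease network from a gene set and a PPI edge table.

    Keeps only edges with both endpoints in ``gene_set`` and confidence >=
    ``min_confidence`` (default 0.4, the STRING "medium confidence"
    convention); self-loops are discarded, duplicate unordered pairs keep the
    highest confidence, and genes left isolated are dropped.
    """
    if not (0.0 <= min_confidence <= 1.0):
        raise ValueError("min_confidence must be in [0, 1]")
    required = {"gene_a", "gene_b", "confidence"}
    if not required.issubset(edges.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    genes = {normalize_gene_id(g) for g in gene_set}

    a = edges["gene_a"].map(normalize_gene_id)
    b = edges["gene_b"].map(normalize_gene_id)
    conf = edges["confidence"].astype(float)
    keep = a.isin(genes) & b.isin(genes) & (conf >= min_confidence) & (a != b)

    graph = nx.Graph()
    for u, v, c in zip(a[keep], b[keep], conf[keep]):
        if graph.has_edge(u, v):
            graph[u][v]["confidence"] = max(graph[u][v]["confidence"], c)
        else:
            graph.add_edge(u, v, confidence=float(c))
    if graph.number_of_edges() == 0:
        raise NetworkBuildError(
            f"no edges survive filtering (min_confidence={min_confidence}, "
            f"{len(edges)} candidate edges, {len(genes)} genes); threshold too high "
            "or gene identifiers do not match")
    return DiseaseNetwork(graph=graph)


def ntra_rank(network: DiseaseNetwork, disease_log2fc: Mapping[str, float] | pd.Series,
              ) -> DiseaseNetwork:
    """Attach the NTRA stand-in score and rank to every node (in place).

    score = z(|disease log2FC|) + z(log(degree + 1)), z-scored over the
    network's nodes.  Rank 1 is the highest score; ties break by gene id.
    A component with zero variance contributes 0 (with a warning) rather
    than an undefined z-score.
    """
    nodes = network.nodes
    try:
        lfc = np.array([float(disease_log2fc[g]) for g in nodes])
    except KeyError as exc:
        raise KeyError(f"disease_log2fc missing for node {exc.args[0]!r}") from None

    def _z(x: np.ndarray, label: str) -> np.ndarray:
        sd = x.std()
        if sd == 0:
            warnings.warn(f"zero variance in {label}; its z-score contribution is set to 0")
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    comp_fc = _z(np.abs(lfc), "|disease log2FC|")
    comp_deg = _z(np.log(np.array([network.graph.degree(g) for g in nodes]) + 1.0), "log(degree+1)")
    score = comp_fc + comp_deg

    order = sorted(range(len(nodes)), key=lambda i: (-score[i], nodes[i]))
    rank = np.empty(len(nodes), dtype=int)
    for r, i in enumerate(order, start=1):
        rank[i] = r
    for i, g in enumerate(nodes):
        network.graph.nodes[g].update(
            disease_log2fc=float(lfc[i]), ntra_score=float(score[i]), ntra_rank=int(rank[i]))
    return network
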