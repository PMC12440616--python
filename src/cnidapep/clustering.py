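"""All-vs-all similarity clustering with a seeded force-directed layout.

Precursor lists are classified the way sequence-cluster maps are built:
every unordered pair of sequences is scored by optimal Smith-Waterman local
alignment (BLOSUM62, affine gaps), scores are converted to e-values with
the ungapped Karlin-Altschul formula E = K*m*n*exp(-lambda*S) (K and lambda
fixed to the standard ungapped BLOSUM62 constants — a documented
approximation, since the alignments are gapped), pairs at or below an
e-value cutoff become edges of an undirected similarity graph, clusters are
the connected components, and a deterministic force-directed layout embeds
the graph in 2D for inspection. Specific coordinates are not meaningful;
determinism under a fixed seed and the separation of unrelated clusters
are the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import UsageError


@dataclass
class LayoutConfig:
    iterations: int = 1000
    attraction: float = 1.0
    repulsion: float = 1.0
    damping: float = 0.9
    min_dist: float = 1e-6
    step: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class ClusterConfig:
    """Alignment scoring, e-value conversion and layout parameters.

    ``karlin_k`` and ``karlin_lambda`` are the ungapped Karlin-Altschul
    constants for BLOSUM62; gap penalties follow the convention that a gap
    of length L costs gap_open + (L-1)*gap_extend.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    e_cutoff: float = 1e-4
    karlin_k: float = 0.041
    karlin_lambda: float = 0.267
    layout: LayoutConfig = field(default_factory=LayoutConfig)

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.e_cutoff <= 0:
            raise ValueError("e_cutoff must be positive")


@dataclass
class SimilarityEdge:
    """One undirected similarity edge, with i < j by id order."""

    i: str
    j: str
    raw_score: float
    e_value: float


@dataclass
class SimilarityGraph:
    nodes: list[str]
    edges: list[SimilarityEdge]
    cluster_labels: dict[str, str] = field(default_factory=dict)
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)


def _aligner(config: ClusterConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(config.substitution_matrix)
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def pairwise_local_score(a: str, b: str, config: Optional[ClusterConfig] = None) -> float:
    """Optimal local-alignment score of two residue strings (symmetric, >= 0)."""
    config = config or ClusterConfig()
    return float(_aligner(config).score(a, b))


def evalue_from_score(
    raw_score: float, m: int, n: int, config: Optional[ClusterConfig] = None
) -> float:
    """Karlin-Altschul expect value E = K*m*n*exp(-lambda*S)."""
    config = config or ClusterConfig()
    return config.karlin_k * m * n * math.exp(-config.karlin_lambda * raw_score)


def build_graph(
    sequences: dict[str, str], config: Optional[ClusterConfig] = None
) -> SimilarityGraph:
    """Score every unordered pair once; keep edges with e-value <= cutoff."""
    config = config or ClusterConfig()
    if len(sequences) < 2:
        raise UsageError("similarity clustering needs at least 2 sequences")
    nodes = sorted(sequences)
    aligner = _aligner(config)
    edges: list[SimilarityEdge] = []
    for idx, i in enumerate(nodes):
        for j in nodes[idx + 1:]:
            score = float(aligner.score(sequences[i], sequences[j]))
            e = evalue_from_score(score, len(sequences[i]), len(sequences[j]), config)
            if e <= config.e_cutoff:
                edges.append(SimilarityEdge(i=i, j=j, raw_score=score, e_value=e))
    edges.sort(key=lambda e: (e.i, e.j))
    return SimilarityGraph(nodes=nodes, edges=edges)


def connected_clusters(graph: SimilarityGraph) -> dict[str, str]:
    """Label connected components; singletons are labelled "singleton".

    Components are ordered by decreasing size, ties by smallest member id,
    and labelled cluster_0, cluster_1, ... — invariant under node input
    order.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from((e.i, e.j) for e in graph.edges)
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    labels: dict[str, str] = {}
    k = 0
    for comp in components:
        if len(comp) == 1:
            labels[comp[0]] = "singleton"
        else:
            for node in comp:
                labels[node] = f"cluster_{k}"
            k += 1
    graph.cluster_labels = labels
    return labels


def edge_weight(e_value: float) -> float:
    """Attraction weight from an e-value: min(1, -log10(e)/10), floored at 0."""
    if e_value <= 0:  # exp underflow for very high scores
        return 1.0
    return min(1.0, max(0.0, -math.log10(e_value) / 10.0))


def force_layout(
    graph: SimilarityGraph, config: Optional[LayoutConfig] = None
) -> dict[str, tuple[float, float]]:
    """Seeded force-directed 2D embedding of the similarity graph.

    Positions start uniformly at random in the unit square from the seeded
    generator. Each iteration applies, per edge, an attraction proportional
    to the e-value weight times the displacement vector and, per node pair,
    a repulsion inversely proportional to distance, then updates positions
    through a damped velocity. Exactly ``iterations`` steps are run; the
    result is bit-reproducible for a fixed seed.
    """
    config = config or LayoutConfig()
    nodes = graph.nodes
    n = len(nodes)
    index = {node: k for k, node in enumerate(nodes)}
    rng = np.random.default_rng(config.seed)
    pos = rng.uniform(0.0, 1.0, size=(n, 2))
    vel = np.zeros_like(pos)
    edge_idx = np.array([[index[e.i], index[e.j]] for e in graph.edges], dtype=int)
    weights = np.array([edge_weight(e.e_value) for e in graph.edges])

    for _ in range(config.iterations):
        force = np.zeros_like(pos)
        if len(edge_idx):
            disp = pos[edge_idx[:, 1]] - pos[edge_idx[:, 0]]
            pull = config.attraction * weights[:, None] * disp
            np.add.at(force, edge_idx[:, 0], pull)
            np.add.at(force, edge_idx[:, 1], -pull)
        if n > 1:
            delta = pos[:, None, :] - pos[None, :, :]
            dist = np.maximum(np.linalg.norm(delta, axis=-1), config.min_dist)
            np.fill_diagonal(dist, np.inf)
            force += config.repulsion * (delta / dist[..., None] ** 2).sum(axis=1)
        vel = config.damping * (vel + config.step * force)
        pos = pos + vel

    coords = {node: (float(pos[k, 0]), float(pos[k, 1])) for node, k in index.items()}
    graph.coordinates = coords
    return coords


def cluster_sequences(
    sequences: dict[str, str], config: Optional[ClusterConfig] = None
) -> SimilarityGraph:
    """Build the graph, label clusters and lay it out; one-call convenience."""
    config = config or ClusterConfig()
    graph = build_graph(sequences, config)
    connected_clusters(graph)
    force_layout(graph, config.layout)
    return graph


def edge_table(graph: SimilarityGraph) -> pd.DataFrame:
    return pd.DataFrame(
        [{"i": e.i, "j": e.j, "raw_score": e.raw_score, "e_value": e.e_value} for e in graph.edges],
        columns=["i", "j", "raw_score", "e_value"],
    )


def coordinates_table(graph: SimilarityGraph) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": n, "x": graph.coordinates[n][0], "y": graph.coordinates[n][1]} for n in graph.nodes],
        columns=["id", "x", "y"],
    )


def cluster_table(graph: SimilarityGraph) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": n, "cluster_label": graph.cluster_labels[n]} for n in graph.nodes],
        columns=["id", "cluster_label"],
    )
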