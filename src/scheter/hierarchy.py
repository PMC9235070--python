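"""Gene-cluster hierarchies from consensus k-means and their reduction.

Genes are clustered at every resolution ``k = 1..k_max`` with a consensus
k-means procedure: the genes are repeatedly subsampled, k-means is run on
each subsample, pairwise consensus values are accumulated as the fraction of
runs in which two genes landed in the same cluster (among runs where both
were sampled), and an average-linkage agglomerative clustering of the
``1 - consensus`` distances is cut into k groups.

Clusters at consecutive resolutions are tied by an *inheritance* relation:
the cluster ``c_j`` at level ``k+1`` inherits ``c_i`` at level ``k`` when
their overlap is at least 15% of ``|c_j|``.  The clusters plus inheritance
edges form a directed acyclic graph (not a dendrogram: a cluster can have
several parents when it is joined from pieces of several coarser clusters,
and several children when it splits).  Edges here are stored pointing from
the coarser cluster (small k, the root side) to the finer cluster, so paths
run root -> leaves.

Runs of clusters that stay essentially unchanged over a range of k's form
*stumps*: maximal chains whose non-terminal nodes have a single parent and a
single child.  :func:`reduce_hierarchy` collapses every stump into one node
(represented by the deepest cluster of the chain) and rewires the edges
through the collapse map ``f``, yielding the compact reduced hierarchy used
by the enrichment-path and cross-dataset alignment analyses.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .heterogeneity import intra_inter_correlations, nsv_fractions, p_diff, \
    silhouette_values, zscore_cells
from .io_preprocess import ExpressionMatrix

__all__ = [
    "ClusterHierarchy",
    "ReducedHierarchy",
    "consensus_kmeans",
    "build_full_hierarchy",
    "reduce_hierarchy",
    "annotate_clusters",
    "rank_pdiff",
]

INHERIT_THRESHOLD = 0.15


@dataclasses.dataclass
class ClusterHierarchy:
    """DAG of gene clusters across k levels.

    Node attributes: ``level`` (the k at which the cluster was produced),
    ``genes`` (frozenset of members) and optional annotations ``p_diff``,
    ``avg_nsv``, ``density``.  Edges point from the coarser to the finer
    cluster and carry ``weight`` = overlap size over the finer cluster size.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("hierarchy must be acyclic")

    # -- accessors ---------------------------------------------------------

    def genes_of(self, node) -> frozenset:
        return self.graph.nodes[node]["genes"]

    def level_of(self, node) -> int:
        return self.graph.nodes[node]["level"]

    def roots(self) -> list:
        return [v for v in self.graph if self.graph.in_degree(v) == 0]

    def leaves(self) -> list:
        return [v for v in self.graph if self.graph.out_degree(v) == 0]

    def root_leaf_paths(self) -> list[list]:
        """All directed root-to-leaf paths (single-node paths included)."""
        paths = []
        for r in self.roots():
            for l in self.leaves():
                if r == l:
                    paths.append([r])
                else:
                    paths.extend(nx.all_simple_paths(self.graph, r, l))
        return paths

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        nodes = []
        for v, data in self.graph.nodes(data=True):
            entry = {"id": v, "level": data["level"], "genes": sorted(data["genes"])}
            for key in ("p_diff", "avg_nsv", "density"):
                if key in data:
                    entry[key] = data[key]
            nodes.append(entry)
        edges = [
            {"source": u, "target": v, "weight": d.get("weight")}
            for u, v, d in self.graph.edges(data=True)
        ]
        return {"nodes": nodes, "edges": edges}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ClusterHierarchy":
        g = nx.DiGraph()
        for entry in payload["nodes"]:
            attrs = {
                "level": entry["level"],
                "genes": frozenset(entry["genes"]),
            }
            for key in ("p_diff", "avg_nsv", "density"):
                if key in entry and entry[key] is not None:
                    attrs[key] = entry[key]
            g.add_node(entry["id"], **attrs)
        for e in payload["edges"]:
            g.add_edge(e["source"], e["target"], weight=e.get("weight"))
        return cls(g)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClusterHierarchy":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclasses.dataclass
class ReducedHierarchy:
    """Reduced DAG plus the collapse map from full nodes to reduced nodes."""

    hierarchy: ClusterHierarchy
    node_map: dict

    @property
    def graph(self) -> nx.DiGraph:
        return self.hierarchy.graph

    def to_dict(self) -> dict:
        return {
            "hierarchy": self.hierarchy.to_dict(),
            "node_map": {str(k): v for k, v in self.node_map.items()},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ReducedHierarchy":
        payload = json.loads(Path(path).read_text())
        hierarchy = ClusterHierarchy.from_dict(payload["hierarchy"])
        node_map = {}
        for k, v in payload["node_map"].items():
            node_map[int(k) if k.lstrip("-").isdigit() else k] = v
        return cls(hierarchy, node_map)


# ---------------------------------------------------------------------------
# consensus k-means
# ---------------------------------------------------------------------------

def consensus_kmeans(
    m: ExpressionMatrix,
    k: int,
    n_runs: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    return_consensus: bool = False,
):
    """Partition genes into k stable clusters by subsampled k-means.

    Gene vectors are z-scored over cells before clustering so Euclidean
    k-means is not dominated by expression magnitude.  Returns an integer
    label per gene (0..k-1); with ``return_consensus`` also the symmetric
    consensus matrix in [0, 1].
    """
    n_genes = m.n_genes
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_genes:
        raise ValueError(f"k={k} exceeds the number of genes ({n_genes})")
    X = m.values
    sd = X.std(axis=1, ddof=0, keepdims=True)
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    if k == 1:
        labels = np.zeros(n_genes, dtype=int)
        if return_consensus:
            return labels, np.ones((n_genes, n_genes))
        return labels

    rng = np.random.default_rng(seed)
    together = np.zeros((n_genes, n_genes))
    sampled = np.zeros((n_genes, n_genes))
    n_sub = max(int(round(subsample_frac * n_genes)), k)
    for run in range(n_runs):
        idx = rng.choice(n_genes, size=n_sub, replace=False)
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(Z[idx])
        sampled[np.ix_(idx, idx)] += 1.0
        for c in range(k):
            members = idx[km.labels_ == c]
            together[np.ix_(members, members)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(link, t=k, criterion="maxclust") - 1
    if return_consensus:
        return labels, consensus
    return labels


# ---------------------------------------------------------------------------
# full hierarchy construction
# ---------------------------------------------------------------------------

def build_full_hierarchy(
    m: ExpressionMatrix,
    k_max: int = 12,
    inherit_threshold: float = INHERIT_THRESHOLD,
    *,
    n_runs: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    include_root: bool = True,
    clusterings: Mapping[int, Sequence[int]] | None = None,
) -> ClusterHierarchy:
    """Build the gene-cluster DAG over k = 1..k_max.

    Cluster ids are assigned level by level in increasing k.  An edge runs
    from a level-k cluster to a level-(k+1) cluster when their intersection
    covers at least ``inherit_threshold`` of the finer cluster; its weight is
    the covered fraction.  ``clusterings`` may supply precomputed gene labels
    per level (used by the tests' oracles); otherwise consensus k-means is
    run for every level.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    levels = range(1 if include_root else 2, k_max + 1)
    genes = np.asarray(m.genes)
    g = nx.DiGraph()
    next_id = 1
    by_level: dict[int, list[tuple[int, frozenset]]] = {}
    for k in levels:
        if clusterings is not None and k in clusterings:
            labels = np.asarray(clusterings[k])
        else:
            labels = consensus_kmeans(
                m, k, n_runs=n_runs, subsample_frac=subsample_frac, seed=seed + k
            )
        nodes = []
        for c in sorted(set(labels.tolist())):
            members = frozenset(genes[labels == c])
            g.add_node(next_id, level=k, genes=members)
            nodes.append((next_id, members))
            next_id += 1
        by_level[k] = nodes
    for k in levels:
        if k + 1 not in by_level:
            continue
        for ci, gi in by_level[k]:
            for cj, gj in by_level[k + 1]:
                overlap = len(gi & gj)
                if overlap >= inherit_threshold * len(gj):
                    g.add_edge(ci, cj, weight=overlap / len(gj))
    return ClusterHierarchy(g)


# ---------------------------------------------------------------------------
# stump reduction
# ---------------------------------------------------------------------------

def _maximal_chains(g: nx.DiGraph, linear: set) -> list[list]:
    """Maximal chains of linear nodes joined by consecutive edges."""
    chains = []
    seen: set = set()
    for v in g.nodes:
        if v not in linear or v in seen:
            continue
        preds = list(g.predecessors(v))
        # chain start: no predecessor, or predecessor outside the linear set
        if preds and preds[0] in linear and v in set(g.successors(preds[0])):
            continue
        chain = [v]
        seen.add(v)
        while True:
            succs = list(g.successors(chain[-1]))
            if len(succs) == 1 and succs[0] in linear and succs[0] not in seen:
                chain.append(succs[0])
                seen.add(succs[0])
            else:
                break
        chains.append(chain)
    return chains


def reduce_hierarchy(
    g: ClusterHierarchy, representative: str = "bottom"
) -> ReducedHierarchy:
    """Collapse every stump of the hierarchy into a single node.

    Linear nodes (at most one parent and at most one child) are grouped into
    maximal chains; each chain is extended at its bottom by the following
    node when that node has several children or none, and the extended chain
    (the stump) is collapsed.  The collapsed node's gene set is the deepest
    (largest-k) cluster of the stump by default, or the union of its members
    with ``representative="union"``.  Edges are rewired through the collapse
    map; applying the reduction twice gives an isomorphic result.
    """
    if representative not in ("bottom", "union"):
        raise ValueError("representative must be 'bottom' or 'union'")
    graph = g.graph
    linear = {
        v for v in graph if graph.in_degree(v) <= 1 and graph.out_degree(v) <= 1
    }
    chains = _maximal_chains(graph, linear)
    # deterministic order: a shared absorbable bottom goes to the earlier chain
    pos = {v: i for i, v in enumerate(nx.topological_sort(graph))}
    chains.sort(key=lambda c: pos[c[0]])
    # extend each chain at the bottom by a branch/terminal node
    stumps: list[list] = []
    absorbed: set = set()
    for chain in chains:
        succs = list(graph.successors(chain[-1]))
        stump = list(chain)
        if len(succs) == 1:
            nxt = succs[0]
            if graph.out_degree(nxt) != 1 and nxt not in absorbed:
                stump.append(nxt)
        stumps.append(stump)
        absorbed.update(stump)

    reduced = nx.DiGraph()
    node_map: dict = {}
    def node_attrs(v, members):
        attrs = {"level": g.level_of(v), "genes": members}
        for key in ("p_diff", "avg_nsv", "density"):
            if key in graph.nodes[v]:
                attrs[key] = graph.nodes[v][key]
        return attrs

    for stump in stumps:
        rep = stump[-1]
        members = g.genes_of(rep)
        if representative == "union":
            members = frozenset().union(*(g.genes_of(v) for v in stump))
        reduced.add_node(rep, **node_attrs(rep, members))
        for v in stump:
            node_map[v] = rep
    for v in graph:
        if v not in node_map:
            reduced.add_node(v, **node_attrs(v, g.genes_of(v)))
            node_map[v] = v
    for v1, v2, data in graph.edges(data=True):
        u1, u2 = node_map[v1], node_map[v2]
        if u1 != u2:
            w = data.get("weight")
            if reduced.has_edge(u1, u2):
                old = reduced.edges[u1, u2].get("weight")
                if w is not None and (old is None or w > old):
                    reduced.edges[u1, u2]["weight"] = w
            else:
                reduced.add_edge(u1, u2, weight=w)
    return ReducedHierarchy(ClusterHierarchy(reduced), node_map)


# ---------------------------------------------------------------------------
# annotation and ranking
# ---------------------------------------------------------------------------

def annotate_clusters(
    g: ClusterHierarchy,
    m: ExpressionMatrix,
    *,
    epsilon: float = 0.05,
    n_samples: int = 20_000,
    seed: int = 0,
) -> ClusterHierarchy:
    """Attach p_diff, average NSV and density to every cluster node.

    Density is the fraction of observed entries within the cluster's
    submatrix.  p_diff and NSV are computed over the cluster's gene subset;
    clusters with fewer than two genes get NaN statistics (cell-cell
    correlation is undefined there).
    """
    labels = m.tumor_labels()
    for v in g.graph.nodes:
        genes = sorted(g.genes_of(v))
        idx = m.gene_index(genes)
        obs = m.observed[idx]
        g.graph.nodes[v]["density"] = float(obs.mean()) if obs.size else float("nan")
        if len(genes) < 2:
            warnings.warn(f"cluster {v} has fewer than two genes; statistics NaN")
            g.graph.nodes[v]["p_diff"] = float("nan")
            g.graph.nodes[v]["avg_nsv"] = float("nan")
            continue
        sub = m.subset_genes(genes)
        intra, inter = intra_inter_correlations(sub, tumor_of=labels)
        intra, inter = intra[np.isfinite(intra)], inter[np.isfinite(inter)]
        g.graph.nodes[v]["p_diff"] = p_diff(
            intra, inter, epsilon=epsilon, n_samples=n_samples, seed=seed
        )
        try:
            s = silhouette_values(zscore_cells(sub), labels)
            _, avg = nsv_fractions(s, labels)
        except ValueError:
            avg = float("nan")
        g.graph.nodes[v]["avg_nsv"] = avg
    return g


def rank_pdiff(reduced: ReducedHierarchy | ClusterHierarchy) -> dict:
    """Rank clusters by descending p_diff; ties share the average rank."""
    h = reduced.hierarchy if isinstance(reduced, ReducedHierarchy) else reduced
    nodes = list(h.graph.nodes)
    try:
        values = np.array([h.graph.nodes[v]["p_diff"] for v in nodes], dtype=float)
    except KeyError as exc:
        raise ValueError(f"node {exc.args[0]!r} lacks a p_diff annotation") from None
    if np.isnan(values).any():
        bad = nodes[int(np.flatnonzero(np.isnan(values))[0])]
        raise ValueError(f"node {bad!r} has NaN p_diff; cannot rank")
    ranks = rankdata(-values, method="average")
    return {v: float(r) for v, r in zip(nodes, ranks)}
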