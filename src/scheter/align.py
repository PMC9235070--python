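"""Cross-dataset alignment of reduced gene-cluster hierarchies.

Gene clusters from different datasets (cancer types) are grouped into *meta
gene clusters* in three stages that respect each dataset's hierarchical
structure:

**Path matching.**  For every pair of datasets, clusters are declared
overlapping when their Jaccard index exceeds 0.2, or lies in [0.1, 0.2]
while each cluster ranks within the partner dataset's top ten by overlap
ratio.  Contiguous subpaths of the root-to-leaf paths of the two reduced
hierarchies match when more than 90% of their cross cluster pairs overlap;
matched pairs contained in no larger matched pair are *maximally matched*.
Path tops are trimmed when the branches below a shared top are mutually
non-overlapping (the shared root is then uninformative), and maximal paths
of one dataset whose tops coincide and whose partner-side matches also
overlap are merged; cliques of mutually mergeable paths span per-dataset
subgraphs.

**NMF decomposition.**  Per dataset, the subgraphs form a binary
subgraph x edge membership matrix A.  Non-negative matrix factorization
A ~ W.H for K = 2..10 components (multiplicative updates, random
initialization) yields relaxed edge memberships H; rows are quantized at
10% of their maximum, deduplicated, required to hold at least two edges and
to induce a connected piece of the hierarchy.  Components from all datasets
whose member-gene sets overlap by at least 75% of each are clique-merged
into the trial's meta clusters.  (Gene sets, the universe shared by all
datasets, are what makes cross-dataset merging possible.)

**Consensus.**  The NMF initialization is re-randomized over many trials;
each trial yields a cluster co-occurrence matrix, and the trial minimizing
the total Hamming distance to all others (the medoid) is reported.  A
cluster belongs to a meta cluster when it is an endpoint of one of its
edges; clusters touched by no meta cluster are orphans.  An optional
user-supplied merge map can combine meta clusters afterwards.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .hierarchy import ClusterHierarchy, ReducedHierarchy

__all__ = [
    "ClusterOverlap",
    "clusters_overlap",
    "PathMatch",
    "paths_match",
    "match_paths",
    "trim_path_tops",
    "group_mergeable_paths",
    "SubgraphMatrix",
    "Component",
    "nmf_components",
    "MetaCluster",
    "merge_components",
    "MetaClusterAssignment",
    "consensus_meta",
    "align_hierarchies",
    "meta_enrichment_score",
    "meta_pdiff_ranks",
    "select_shared_genesets",
]

JACCARD_HI = 0.2
JACCARD_LO = 0.1
TOP_N = 10
MATCH_FRAC = 0.9
QUANTIZE_FRAC = 0.1
MERGE_FRAC = 0.75
N_TRIALS = 100


def _as_hierarchy(h) -> ClusterHierarchy:
    return h.hierarchy if isinstance(h, ReducedHierarchy) else h


# ---------------------------------------------------------------------------
# cluster overlap
# ---------------------------------------------------------------------------

class ClusterOverlap:
    """Two-tier overlap relation between the clusters of two datasets.

    Precomputes the Jaccard matrix between ``clusters_a`` and ``clusters_b``
    (node -> gene set maps) and the mutual top-N ranking used by the
    moderate-overlap fallback.
    """

    def __init__(
        self,
        clusters_a: Mapping,
        clusters_b: Mapping,
        jaccard_hi: float = JACCARD_HI,
        jaccard_lo: float = JACCARD_LO,
        top_n: int = TOP_N,
    ):
        self.ids_a = list(clusters_a)
        self.ids_b = list(clusters_b)
        na, nb = len(self.ids_a), len(self.ids_b)
        J = np.zeros((na, nb))
        for i, a in enumerate(self.ids_a):
            ga = set(clusters_a[a])
            for j, b in enumerate(self.ids_b):
                gb = set(clusters_b[b])
                union = len(ga | gb)
                J[i, j] = len(ga & gb) / union if union else 0.0
        self.jaccard = J
        self._pos_a = {a: i for i, a in enumerate(self.ids_a)}
        self._pos_b = {b: j for j, b in enumerate(self.ids_b)}
        # top-N partner ranks; ties resolved by descending Jaccard then index
        order_b = np.argsort(-J, axis=1, kind="stable")
        order_a = np.argsort(-J, axis=0, kind="stable")
        top_b = {i: set(order_b[i, :top_n].tolist()) for i in range(na)}
        top_a = {j: set(order_a[:top_n, j].tolist()) for j in range(nb)}
        self._overlap = np.zeros((na, nb), dtype=bool)
        for i in range(na):
            for j in range(nb):
                if J[i, j] > jaccard_hi:
                    self._overlap[i, j] = True
                elif J[i, j] >= jaccard_lo:
                    self._overlap[i, j] = j in top_b[i] and i in top_a[j]

    def overlap(self, a, b) -> bool:
        return bool(self._overlap[self._pos_a[a], self._pos_b[b]])


def clusters_overlap(
    c1: set,
    c2: set,
    jaccard_hi: float = JACCARD_HI,
    jaccard_lo: float = JACCARD_LO,
    top_n: int = TOP_N,
    context_a: Mapping | None = None,
    context_b: Mapping | None = None,
) -> bool:
    """Two-tier overlap decision for a single cluster pair.

    The moderate-overlap fallback needs the other clusters of both datasets
    (``context_a``/``context_b``, node -> gene set maps including the two
    clusters under test as entries ``0``); without context the fallback's
    top-N condition holds vacuously.
    """
    ctx_a = dict(context_a) if context_a else {0: set(c1)}
    ctx_b = dict(context_b) if context_b else {0: set(c2)}
    key_a = next(k for k, v in ctx_a.items() if set(v) == set(c1))
    key_b = next(k for k, v in ctx_b.items() if set(v) == set(c2))
    oracle = ClusterOverlap(ctx_a, ctx_b, jaccard_hi, jaccard_lo, top_n)
    return oracle.overlap(key_a, key_b)


# ---------------------------------------------------------------------------
# path matching
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PathMatch:
    """A maximally matched pair of hierarchy subpaths from two datasets."""

    dataset_a: int
    dataset_b: int
    path_a: tuple
    path_b: tuple
    matched: bool = True
    maximal: bool = True


def paths_match(
    path_a: Sequence, path_b: Sequence, oracle: ClusterOverlap, frac: float = MATCH_FRAC
) -> bool:
    """True when more than ``frac`` of the cross cluster pairs overlap."""
    pairs = [(u, v) for u in path_a for v in path_b]
    hits = sum(oracle.overlap(u, v) for u, v in pairs)
    return hits > frac * len(pairs)


def _subpaths(path: Sequence) -> list[tuple]:
    n = len(path)
    return [tuple(path[i:j]) for i in range(n) for j in range(i + 1, n + 1)]


def _contains(big: tuple, small: tuple) -> bool:
    n, m = len(big), len(small)
    return any(big[i : i + m] == small for i in range(n - m + 1))


def match_paths(
    hier_a,
    hier_b,
    oracle: ClusterOverlap,
    *,
    dataset_a: int = 0,
    dataset_b: int = 1,
    frac: float = MATCH_FRAC,
) -> list[PathMatch]:
    """All maximally matched subpath pairs between two reduced hierarchies."""
    ha, hb = _as_hierarchy(hier_a), _as_hierarchy(hier_b)
    paths_a = sorted({tuple(p) for p in ha.root_leaf_paths()})
    paths_b = sorted({tuple(p) for p in hb.root_leaf_paths()})
    pos_a = {v: i for i, v in enumerate(oracle.ids_a)}
    pos_b = {v: j for j, v in enumerate(oracle.ids_b)}
    overlap_matrix = oracle._overlap.astype(np.int64)
    matched_set: set[tuple] = set()
    for pa in paths_a:
        ia = np.array([pos_a[v] for v in pa])
        for pb in paths_b:
            jb = np.array([pos_b[v] for v in pb])
            la, lb = len(pa), len(pb)
            # 2-D prefix sums give every contiguous subpath pair's hit
            # count; all (i1, i2] x (j1, j2] windows are tested at once
            S = np.zeros((la + 1, lb + 1), dtype=np.int64)
            S[1:, 1:] = overlap_matrix[np.ix_(ia, jb)].cumsum(0).cumsum(1)
            i1, i2 = np.tril_indices(la + 1, k=-1)  # i2 < i1: swap to get i1 < i2
            i1, i2 = i2, i1
            j1, j2 = np.tril_indices(lb + 1, k=-1)
            j1, j2 = j2, j1
            counts = (
                S[np.ix_(i2, j2)] - S[np.ix_(i1, j2)]
                - S[np.ix_(i2, j1)] + S[np.ix_(i1, j1)]
            )
            areas = np.outer(i2 - i1, j2 - j1)
            hits = np.argwhere(counts > frac * areas)
            for r, c in hits:
                matched_set.add(
                    (pa[i1[r] : i2[r]], pb[j1[c] : j2[c]])
                )
    matched = list(matched_set)
    # a pair contained in any matched pair is contained in a maximal one,
    # so processing by descending size needs containment checks against the
    # accepted maximal pairs only
    matched.sort(key=lambda pq: -(len(pq[0]) + len(pq[1])))
    maximal: list[tuple] = []
    for pa, pb in matched:
        bigger = any(
            _contains(qa, pa) and _contains(qb, pb) for qa, qb in maximal
        )
        if not bigger:
            maximal.append((pa, pb))
    return [PathMatch(dataset_a, dataset_b, pa, pb) for pa, pb in maximal]


def _poorly_overlapped(clusters_x: Sequence, clusters_y: Sequence, oracle) -> bool:
    """More than half of the cross cluster pairs do not overlap."""
    pairs = [(x, y) for x in clusters_x for y in clusters_y]
    if not pairs:
        return False
    misses = sum(not oracle.overlap(x, y) for x, y in pairs)
    return misses > 0.5 * len(pairs)


def trim_path_tops(
    matches: list[PathMatch],
    hier_a,
    hier_b,
    oracle: ClusterOverlap,
) -> list[PathMatch]:
    """Drop uninformative shared top nodes from maximally matched paths.

    A path's top node carries no alignment information when the sibling
    branches hanging from it (complementary root-leaf paths of the same
    hierarchy: same top, disjoint below) do not overlap the path's
    partner-side matches below their tops — the shared top is then a
    coarse ancestor gluing unrelated lineages, and it is removed.  Top
    nodes are trimmed repeatedly until the condition fails; applied to
    both sides, with emptied or duplicated matches dropped.
    """
    def complementary_below(hier, path) -> list:
        top = path[0]
        below = set(path[1:])
        out = set()
        for q in _as_hierarchy(hier).root_leaf_paths():
            if top in q:
                tail = q[q.index(top) + 1 :]
                if tail and not set(tail) & below:
                    out.update(tail)
        return sorted(out)

    def trim_side(side: str) -> None:
        for i, match in enumerate(matches):
            while True:
                path = match.path_a if side == "a" else match.path_b
                if len(path) < 2:
                    break
                hier = hier_a if side == "a" else hier_b
                comp_below = complementary_below(hier, path)
                partner = [
                    other.path_b if side == "a" else other.path_a
                    for other in matches
                    if (other.path_a if side == "a" else other.path_b) == path
                ]
                part_below = sorted({v for q in partner for v in q if v != q[0]})
                if not comp_below or not part_below:
                    break
                if side == "a":
                    poor = _poorly_overlapped(comp_below, part_below, oracle)
                else:
                    poor = _poorly_overlapped(part_below, comp_below, oracle)
                if not poor:
                    break
                trimmed = path[1:]
                if side == "a":
                    match = dataclasses.replace(match, path_a=trimmed)
                else:
                    match = dataclasses.replace(match, path_b=trimmed)
                matches[i] = match

    matches = list(matches)
    trim_side("a")
    trim_side("b")
    out, seen = [], set()
    for match in matches:
        if not match.path_a or not match.path_b:
            continue
        key = (match.path_a, match.path_b)
        if key not in seen:
            seen.add(key)
            out.append(match)
    return out


# ---------------------------------------------------------------------------
# mergeable paths and subgraphs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SubgraphMatrix:
    """Binary subgraph x edge membership matrix for one dataset."""

    dataset: int
    edges: list[tuple]           # edge order defining the columns
    matrix: np.ndarray           # (n_subgraphs, n_edges) of {0, 1}
    subgraph_nodes: list[frozenset]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.size and not (self.matrix.sum(axis=1) >= 1).all():
            raise ValueError("every subgraph row needs at least one edge")


def group_mergeable_paths(
    matches_by_pair: Mapping[tuple[int, int], list[PathMatch]],
    hierarchies: Sequence,
    *,
    self_oracles: Mapping[int, ClusterOverlap] | None = None,
    frac: float = MATCH_FRAC,
) -> list[SubgraphMatrix]:
    """Per-dataset subgraphs from cliques of mutually mergeable maximal paths.

    Two maximal paths of one dataset are mergeable when their top nodes
    coincide and, in at least one partner dataset, a matched path of each
    exists such that the two matched paths overlap at the matching level
    (>90% of their cross cluster pairs, judged by that dataset's
    self-overlap relation).  ``self_oracles`` maps dataset index to the
    overlap relation of the dataset with itself.
    """
    n_datasets = len(hierarchies)
    if self_oracles is None:
        self_oracles = {}
        for d, h in enumerate(hierarchies):
            clusters = {
                v: _as_hierarchy(h).genes_of(v) for v in _as_hierarchy(h).graph.nodes
            }
            self_oracles[d] = ClusterOverlap(clusters, clusters)

    # collect maximal paths and their partner-side matches per dataset
    paths_of: dict[int, list[tuple]] = {d: [] for d in range(n_datasets)}
    partner_matches: dict[tuple[int, tuple], dict[int, list[tuple]]] = {}
    for (da, db), matches in matches_by_pair.items():
        for match in matches:
            for d, path, e, other in (
                (da, match.path_a, db, match.path_b),
                (db, match.path_b, da, match.path_a),
            ):
                if path not in paths_of[d]:
                    paths_of[d].append(path)
                partner_matches.setdefault((d, path), {}).setdefault(e, []).append(other)

    out = []
    for d in range(n_datasets):
        paths = paths_of[d]
        merge_graph = nx.Graph()
        merge_graph.add_nodes_from(range(len(paths)))
        for i, j in itertools.combinations(range(len(paths)), 2):
            p1, p2 = paths[i], paths[j]
            if p1[0] != p2[0]:
                continue
            m1 = partner_matches.get((d, p1), {})
            m2 = partner_matches.get((d, p2), {})
            mergeable = False
            for e in set(m1) & set(m2):
                oracle = self_oracles[e]
                if any(
                    paths_match(q1, q2, oracle, frac)
                    for q1 in m1[e]
                    for q2 in m2[e]
                ):
                    mergeable = True
                    break
            if mergeable:
                merge_graph.add_edge(i, j)
        cliques = sorted(
            (sorted(c) for c in nx.find_cliques(merge_graph)), key=tuple
        )
        graph = _as_hierarchy(hierarchies[d]).graph
        edge_order = sorted(graph.edges())
        edge_pos = {e: i for i, e in enumerate(edge_order)}
        rows, node_sets = [], []
        for clique in cliques:
            nodes = frozenset(v for i in clique for v in paths[i])
            edges = {
                (p[i], p[i + 1])
                for ci in clique
                for p in [paths[ci]]
                for i in range(len(p) - 1)
            }
            if not edges:
                continue  # single-node paths span no edges
            row = np.zeros(len(edge_order), dtype=int)
            for e in edges:
                row[edge_pos[e]] = 1
            rows.append(row)
            node_sets.append(nodes)
        matrix = np.array(rows, dtype=int) if rows else np.zeros((0, len(edge_order)), int)
        out.append(SubgraphMatrix(d, edge_order, matrix, node_sets))
    return out


# ---------------------------------------------------------------------------
# NMF components
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Component:
    """A candidate meta-cluster building block: an edge set of one dataset."""

    dataset: int
    edges: frozenset            # edges of the dataset's reduced hierarchy

    def nodes(self) -> frozenset:
        return frozenset(v for e in self.edges for v in e)


def nmf_components(
    A: SubgraphMatrix,
    k_range: Sequence[int] = range(2, 11),
    quantize_frac: float = QUANTIZE_FRAC,
    seed: int = 0,
    init: str = "nndsvdar",
) -> list[Component]:
    """Decompose the subgraph membership matrix into connected edge sets.

    For every K in ``k_range`` the matrix is factorized (A ~ W.H, Frobenius
    objective, multiplicative updates, randomized per-K initialization;
    the nndsvdar default fills an SVD-based starting point with random
    values and avoids the union-of-components local minima that plain
    uniform starts fall into), each component row of H is quantized at
    ``quantize_frac`` of its maximum, and the unique rows with at least two
    edges whose edges induce a single connected piece of the hierarchy are
    kept.
    """
    if A.matrix.size == 0:
        return []
    seen: set[frozenset] = set()
    out: list[Component] = []
    rng = np.random.default_rng(seed)
    for K in k_range:
        # SVD-based starts need K within the matrix rank budget
        k_init = init if K <= min(A.matrix.shape) else "random"
        model = NMF(
            n_components=K,
            init=k_init,
            solver="mu",
            beta_loss="frobenius",
            max_iter=500,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(A.matrix.astype(float))
        H = model.components_
        for row in H:
            peak = row.max()
            if peak <= 0:
                continue
            mask = row >= quantize_frac * peak
            if mask.sum() < 2:
                continue
            edges = frozenset(e for e, m in zip(A.edges, mask) if m)
            if edges in seen:
                continue
            undirected = nx.Graph(list(edges))
            if nx.number_connected_components(undirected) != 1:
                continue
            seen.add(edges)
            out.append(Component(A.dataset, edges))
    return out


# ---------------------------------------------------------------------------
# merging components into meta clusters
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MetaCluster:
    """One meta gene cluster: merged components and their member clusters."""

    components: tuple
    clusters: frozenset          # of (dataset, node)

    def genes(self, hierarchies: Sequence) -> set:
        out: set = set()
        for d, v in self.clusters:
            out |= set(_as_hierarchy(hierarchies[d]).genes_of(v))
        return out


def _component_genes(comp: Component, hierarchies: Sequence) -> frozenset:
    h = _as_hierarchy(hierarchies[comp.dataset])
    return frozenset(g for v in comp.nodes() for g in h.genes_of(v))


def merge_components(
    components: Sequence[Component],
    hierarchies: Sequence,
    merge_frac: float = MERGE_FRAC,
) -> list[MetaCluster]:
    """Clique-merge components whose gene sets mutually overlap >= 75%.

    Overlap is measured on the member-gene sets induced by each component's
    edges (the universe shared across datasets); a pair is mergeable when
    the intersection covers at least ``merge_frac`` of each side.  Maximal
    cliques of the mergeable relation become meta clusters; a cluster
    belongs to a meta cluster when it is an endpoint of one of its edges.
    """
    comps = list(components)
    genes = [_component_genes(c, hierarchies) for c in comps]
    g = nx.Graph()
    g.add_nodes_from(range(len(comps)))
    for i, j in itertools.combinations(range(len(comps)), 2):
        inter = len(genes[i] & genes[j])
        if (
            genes[i]
            and genes[j]
            and inter >= merge_frac * len(genes[i])
            and inter >= merge_frac * len(genes[j])
        ):
            g.add_edge(i, j)
    cliques = sorted((sorted(c) for c in nx.find_cliques(g)), key=tuple)
    out = []
    for clique in cliques:
        members = tuple(comps[i] for i in clique)
        clusters = frozenset(
            (c.dataset, v) for c in members for v in c.nodes()
        )
        out.append(MetaCluster(members, clusters))
    return out


# ---------------------------------------------------------------------------
# consensus over trials
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MetaClusterAssignment:
    """Final many-to-many map from (dataset, cluster) to meta cluster ids."""

    assignments: dict            # (dataset, node) -> set of meta ids
    meta_clusters: dict          # meta id -> MetaCluster
    trial_id: int
    universe: frozenset          # all (dataset, node) reduced clusters

    def orphans(self) -> set:
        return {c for c in self.universe if not self.assignments.get(c)}

    def members(self, meta_id: int) -> set:
        return {c for c, ids in self.assignments.items() if meta_id in ids}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (d, v) in sorted(self.universe):
            ids = sorted(self.assignments.get((d, v), set()))
            rows.append(
                {
                    "dataset": d,
                    "cluster": v,
                    "meta_ids": ",".join(map(str, ids)),
                    "orphan": int(not ids),
                }
            )
        return pd.DataFrame(rows)


def _cooccurrence(trial: Sequence[MetaCluster], universe: Sequence) -> np.ndarray:
    pos = {c: i for i, c in enumerate(universe)}
    n = len(universe)
    M = np.zeros((n, n), dtype=bool)
    for meta in trial:
        idx = [pos[c] for c in meta.clusters if c in pos]
        for i in idx:
            M[i, idx] = True
    np.fill_diagonal(M, False)
    return M


def consensus_meta(
    trials: Sequence[Sequence[MetaCluster]],
    universe: Sequence | None = None,
    merge_map: Mapping[int, int] | None = None,
) -> MetaClusterAssignment:
    """Select the medoid trial by Hamming distance of co-occurrence matrices.

    ``universe`` lists all (dataset, cluster) pairs of the reduced
    hierarchies (defaults to every cluster named by any trial).  The medoid
    trial's meta clusters are numbered 1..n; ``merge_map`` (old id -> new
    id) may combine them afterwards, mirroring a curation step that is never
    automated.
    """
    if not trials:
        raise ValueError("need at least one trial")
    if universe is None:
        universe = sorted(
            {c for trial in trials for meta in trial for c in meta.clusters}
        )
    universe = list(universe)
    mats = [_cooccurrence(t, universe) for t in trials]
    n = len(trials)
    total = np.zeros(n)
    for i, j in itertools.combinations(range(n), 2):
        d = np.count_nonzero(mats[i] != mats[j])
        total[i] += d
        total[j] += d
    best = int(np.argmin(total))
    chosen = trials[best]
    meta_clusters = {i + 1: m for i, m in enumerate(chosen)}
    if merge_map:
        merged: dict[int, list[MetaCluster]] = {}
        for old, m in meta_clusters.items():
            merged.setdefault(merge_map.get(old, old), []).append(m)
        meta_clusters = {
            new: MetaCluster(
                tuple(c for m in ms for c in m.components),
                frozenset().union(*(m.clusters for m in ms)),
            )
            for new, ms in merged.items()
        }
    assignments: dict = {c: set() for c in universe}
    for mid, meta in meta_clusters.items():
        for c in meta.clusters:
            assignments.setdefault(c, set()).add(mid)
    return MetaClusterAssignment(
        assignments, meta_clusters, best, frozenset(universe)
    )


def align_hierarchies(
    hierarchies: Sequence,
    *,
    n_trials: int = N_TRIALS,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    merge_map: Mapping[int, int] | None = None,
    match_frac: float = MATCH_FRAC,
    merge_frac: float = MERGE_FRAC,
) -> MetaClusterAssignment:
    """End-to-end alignment of several reduced hierarchies.

    Path matching, trimming and subgraph construction are deterministic and
    computed once; the NMF decomposition and merging are repeated for
    ``n_trials`` random initializations and the consensus (medoid) trial is
    returned.
    """
    hiers = [_as_hierarchy(h) for h in hierarchies]
    cluster_maps = [
        {v: h.genes_of(v) for v in h.graph.nodes} for h in hiers
    ]
    matches_by_pair = {}
    for da, db in itertools.combinations(range(len(hiers)), 2):
        oracle = ClusterOverlap(cluster_maps[da], cluster_maps[db])
        matches = match_paths(
            hiers[da], hiers[db], oracle, dataset_a=da, dataset_b=db, frac=match_frac
        )
        matches_by_pair[(da, db)] = trim_path_tops(
            matches, hiers[da], hiers[db], oracle
        )
    subgraphs = group_mergeable_paths(matches_by_pair, hiers, frac=match_frac)
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        components: list[Component] = []
        for A in subgraphs:
            components.extend(
                nmf_components(
                    A, k_range=k_range, seed=int(rng.integers(2**31 - 1))
                )
            )
        trials.append(merge_components(components, hiers, merge_frac=merge_frac))
    universe = sorted(
        (d, v) for d, h in enumerate(hiers) for v in h.graph.nodes
    )
    return consensus_meta(trials, universe=universe, merge_map=merge_map)


# ---------------------------------------------------------------------------
# meta cluster characterization
# ---------------------------------------------------------------------------

def meta_enrichment_score(
    assignment: MetaClusterAssignment,
    meta_id: int,
    dataset: int,
    hierarchy,
    adjusted_p: Mapping,
    *,
    min_path_len: int = 3,
    p_cut: float = 1e-3,
) -> float | None:
    """Enrichment score of one gene set for a meta cluster in one dataset.

    The subgraph spanned by the meta cluster's member clusters is made
    connected by adding minimal connecting paths from the hierarchy, nodes
    claimed exclusively by other meta clusters are removed, and maximal
    directed paths with at least ``min_path_len`` nodes all significant at
    ``p_cut`` are collected.  The score is the geometric mean of the
    ``-log10`` adjusted p-values over the union of those paths' nodes; None
    when no qualifying path exists.
    """
    h = _as_hierarchy(hierarchy)
    members = {v for (d, v) in assignment.members(meta_id) if d == dataset}
    if not members:
        return None
    nodes = set(members)
    und = h.graph.to_undirected(as_view=True)
    # connect components with minimal paths through the hierarchy
    comps = [set(c) & nodes for c in nx.connected_components(und.subgraph(nodes))]
    comps = [c for c in comps if c]
    while len(comps) > 1:
        best = None
        for a, b in itertools.combinations(range(len(comps)), 2):
            for u in comps[a]:
                for v in comps[b]:
                    try:
                        path = nx.shortest_path(und, u, v)
                    except nx.NetworkXNoPath:
                        continue
                    if best is None or len(path) < len(best[0]):
                        best = (path, a, b)
        if best is None:
            break
        path, a, b = best
        nodes.update(path)
        merged = comps[a] | comps[b] | set(path)
        comps = [c for i, c in enumerate(comps) if i not in (a, b)] + [merged]
    # drop nodes claimed exclusively by other meta clusters
    drop = {
        v
        for v in nodes
        if assignment.assignments.get((dataset, v))
        and meta_id not in assignment.assignments[(dataset, v)]
    }
    nodes -= drop
    sub = h.graph.subgraph(nodes)
    good = {v for v in sub if adjusted_p.get(v, 1.0) <= p_cut}
    gsub = sub.subgraph(good)
    if not good:
        return None
    selected: set = set()
    starts = [v for v in gsub if gsub.in_degree(v) == 0]
    ends = {v for v in gsub if gsub.out_degree(v) == 0}
    for s in starts:
        for t in ends:
            if s == t:
                if min_path_len <= 1:
                    selected.add(s)
                continue
            for path in nx.all_simple_paths(gsub, s, t):
                if len(path) >= min_path_len:
                    selected.update(path)
    if not selected:
        return None
    scores = np.array(
        [-np.log10(max(adjusted_p[v], 1e-300)) for v in selected], dtype=float
    )
    if (scores <= 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(scores))))


def meta_pdiff_ranks(
    assignment: MetaClusterAssignment, ranks_by_dataset: Mapping[int, Mapping]
) -> dict[int, float]:
    """Average homogeneity rank of each meta cluster's member clusters.

    Ranks are the per-dataset descending-p_diff ranks of reduced clusters;
    member ranks are pooled over datasets with equal weight.  Meta clusters
    with no ranked member are omitted.
    """
    out: dict[int, float] = {}
    for mid in assignment.meta_clusters:
        pool = [
            ranks_by_dataset[d][v]
            for (d, v) in assignment.members(mid)
            if d in ranks_by_dataset and v in ranks_by_dataset[d]
        ]
        if pool:
            out[mid] = float(np.mean(pool))
    return out


def select_shared_genesets(
    scores: pd.DataFrame,
    min_datasets: int = 2,
    p_cut: float = 1e-3,
    focal: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Gene sets significant in >= ``min_datasets`` datasets for some meta.

    ``scores`` has a MultiIndex (meta_id, dataset) on rows and gene sets on
    columns, holding adjusted p-values (NaN = absent).  Returns a frame with
    the selected sets; when ``focal=(a, b)`` is given, each set is placed in
    group 1 (significant in more datasets of meta a than b), group 2 (the
    converse) or group 3, the sort key for display.
    """
    sig = scores <= p_cut
    counts = sig.groupby(level=0).sum()
    keep = [c for c in scores.columns if (counts[c] >= min_datasets).any()]
    result = pd.DataFrame(index=keep)
    result["max_datasets"] = [counts[c].max() for c in keep]
    if focal is not None:
        a, b = focal
        ca = counts.loc[a] if a in counts.index else pd.Series(0, index=scores.columns)
        cb = counts.loc[b] if b in counts.index else pd.Series(0, index=scores.columns)
        group = np.where(
            ca[keep] > cb[keep], 1, np.where(cb[keep] > ca[keep], 2, 3)
        )
        result["group"] = group
        result = result.sort_values(["group", "max_datasets"], ascending=[True, False])
    return result
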