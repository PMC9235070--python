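"""Hypergeometric gene-set enrichment and unique-enrichment path analysis.

Enrichment of a gene set in a gene cluster is the upper-tail hypergeometric
probability of drawing at least the observed overlap when sampling the
cluster from the universe.  P-values are Benjamini-Hochberg adjusted, by
default within each cluster (one testing family per cluster, one test per
gene set), optionally globally.

Because clusters along an inheritance path overlap heavily, their enrichment
p-values are strongly correlated; a gene set significant in a coarse cluster
is often significant only because of one sub-lineage.  The *unique
enrichment* procedure resolves this: clusters are sorted by their
``-log10`` adjusted p-value, the top-ranking clusters are accumulated while
they stay on a common root-to-leaf path, the maximal path spanned by the
accumulated clusters is extracted (with guards for ambiguous siblings and
low-scoring holes) and possibly extended one node at a time up- or
downstream when exactly one neighbour has both a competitive rank and a
score above the reporting threshold.  The deepest node of the resulting
path, if it scores at least the threshold, is reported as the cluster in
which the gene set is uniquely enriched.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .hierarchy import ClusterHierarchy
from .io_preprocess import GeneSetCollection

__all__ = [
    "EnrichmentTable",
    "hypergeom_enrich",
    "fdr_adjust",
    "enrichment_table",
    "unique_enrichment",
    "UniqueEnrichmentConfig",
]

#: -log10 score a cluster must reach to be reported as uniquely enriched,
#: and below which (together with the halving rule) traversal stops.
SCORE_THRESHOLD = 5.0
#: Rank slack when extending the maximal path.
RANK_SLACK = 5


@dataclasses.dataclass
class EnrichmentTable:
    """Cluster x gene-set matrices of raw and adjusted hypergeometric p-values."""

    raw_p: pd.DataFrame      # clusters x sets
    adjusted: pd.DataFrame   # same shape, BH-adjusted

    @property
    def score(self) -> pd.DataFrame:
        """-log10 of the adjusted p-values (clipped to avoid -log10(0))."""
        return -np.log10(self.adjusted.clip(lower=1e-300))


def hypergeom_enrich(cluster: set, geneset: set, universe: set) -> float:
    """Upper-tail hypergeometric p-value P(overlap >= observed)."""
    if not universe:
        raise ValueError("empty universe")
    cluster = set(cluster) & set(universe)
    geneset = set(geneset) & set(universe)
    M, n, N = len(universe), len(geneset), len(cluster)
    k = len(cluster & geneset)
    return float(hypergeom.sf(k - 1, M, n, N))


def fdr_adjust(raw_p: pd.DataFrame, scope: str = "per-cluster") -> pd.DataFrame:
    """Benjamini-Hochberg adjustment of a cluster x set p-value matrix.

    ``scope="per-cluster"`` treats each cluster's row as one testing family;
    ``scope="global"`` pools the whole matrix.
    """
    values = raw_p.to_numpy(dtype=float)
    if ((values < 0) | (values > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.empty_like(values)
    if scope == "per-cluster":
        for i in range(values.shape[0]):
            out[i] = multipletests(values[i], method="fdr_bh")[1]
    elif scope == "global":
        out = multipletests(values.ravel(), method="fdr_bh")[1].reshape(values.shape)
    else:
        raise ValueError(f"unknown FDR scope {scope!r}")
    return pd.DataFrame(out, index=raw_p.index, columns=raw_p.columns)


def enrichment_table(
    g: ClusterHierarchy,
    collection: GeneSetCollection,
    universe: set | None = None,
    scope: str = "per-cluster",
) -> EnrichmentTable:
    """Hypergeometric enrichment of every gene set in every cluster.

    The universe defaults to the union of all cluster members (the genes
    that survived preprocessing in the dataset).
    """
    nodes = list(g.graph.nodes)
    if universe is None:
        universe = set().union(*(g.genes_of(v) for v in nodes))
    names = list(collection.sets)
    raw = np.empty((len(nodes), len(names)))
    for i, v in enumerate(nodes):
        members = set(g.genes_of(v))
        for j, name in enumerate(names):
            raw[i, j] = hypergeom_enrich(members, collection.sets[name], universe)
    raw_df = pd.DataFrame(raw, index=nodes, columns=names)
    return EnrichmentTable(raw_df, fdr_adjust(raw_df, scope=scope))


# ---------------------------------------------------------------------------
# unique enrichment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class UniqueEnrichmentConfig:
    score_threshold: float = SCORE_THRESHOLD
    rank_slack: int = RANK_SLACK


def _sorted_clusters(scores: Mapping) -> list:
    """Clusters by descending score; ties broken by smaller cluster id."""
    return sorted(scores, key=lambda v: (-scores[v], str(v)))


def _spanned_subpath(path: list, members: set) -> list:
    """Contiguous subpath from the first to the last member of ``members``."""
    pos = [i for i, v in enumerate(path) if v in members]
    return path[pos[0] : pos[-1] + 1] if pos else []


def _holes(path: list, members: set, scores: Mapping, min_score: float) -> bool:
    """True if the spanned stretch contains a non-member scoring below the set."""
    span = _spanned_subpath(path, members)
    return any(v not in members and scores[v] < min_score for v in span)


def _member_runs(path: list, members: set) -> list[list]:
    """All maximal contiguous runs of member clusters along the path."""
    runs: list[list] = []
    current: list = []
    for v in path:
        if v in members:
            current.append(v)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def unique_enrichment(
    g: ClusterHierarchy,
    adjusted_p: Mapping,
    config: UniqueEnrichmentConfig | None = None,
):
    """Cluster in which a gene set is uniquely enriched, or None.

    ``adjusted_p`` maps every cluster node to its FDR-adjusted p-value for
    the gene set under consideration.  The return value is the deepest node
    of the extracted maximal path when its ``-log10`` score reaches the
    reporting threshold (default 5), otherwise None.
    """
    cfg = config or UniqueEnrichmentConfig()
    nodes = list(g.graph.nodes)
    missing = [v for v in nodes if v not in adjusted_p]
    if missing:
        raise ValueError(f"nodes without scores: {missing[:5]}")
    scores = {v: float(-np.log10(max(adjusted_p[v], 1e-300))) for v in nodes}
    order = _sorted_clusters(scores)
    rank = {v: i + 1 for i, v in enumerate(order)}
    all_paths = g.root_leaf_paths()
    if not all_paths:
        raise ValueError("hierarchy has no root-to-leaf paths")

    # accumulate top-ranking clusters that stay on a common root-leaf path
    L: list = [order[0]]
    P = [p for p in all_paths if order[0] in p]
    if not P:
        return None
    completed = False
    for c in order[1:]:
        if not any(c in p for p in P):
            break
        # the sharp-drop stop wins over path completion: a weakly scoring
        # cluster never joins the top-ranking list even when it is a leaf
        if scores[c] < 0.5 * scores[L[-1]] and scores[c] < cfg.score_threshold:
            break
        if any(set(p) <= set(L) | {c} for p in P):
            L.append(c)
            P = [p for p in P if c in p]
            completed = True
            break
        L.append(c)
        P = [p for p in P if c in p]

    # extract the maximal path
    members = set(L)
    maximal: list = []
    if completed or any(set(p) <= members for p in P):
        maximal = next(p for p in P if set(p) <= members)
    else:
        nxt = next((c for c in order if c not in members and any(c in p for p in P)), None)
        if (
            nxt is not None
            and L
            and set(g.graph.predecessors(nxt)) & set(g.graph.predecessors(L[-1]))
            and scores[nxt] > 0.5 * scores[L[-1]]
            and scores[nxt] > cfg.score_threshold
        ):
            L = L[:-1]
            members = set(L)
        if not members:
            return None
        min_score = min(scores[v] for v in members)
        holed = [p for p in P if _holes(p, members, scores, min_score)]
        if len(holed) == len(P):
            runs = [r for p in P for r in _member_runs(p, members)]
            if not runs:
                return None
            maximal = max(runs, key=lambda r: (len(r), -min(rank[v] for v in r)))
        else:
            clean = next(p for p in P if p not in holed)
            maximal = _spanned_subpath(clean, members)
    if not maximal:
        return None

    # extend the maximal path while a single neighbour qualifies
    def qualifies(v, limit):
        return rank[v] < limit and scores[v] >= cfg.score_threshold

    while True:
        limit = max(rank[v] for v in maximal) + cfg.rank_slack
        parents = list(g.graph.predecessors(maximal[0]))
        good = [p for p in parents if qualifies(p, limit)]
        if len(good) == 1 and good[0] not in maximal:
            maximal.insert(0, good[0])
        else:
            break
    while True:
        limit = max(rank[v] for v in maximal) + cfg.rank_slack
        children = list(g.graph.successors(maximal[-1]))
        good = [c for c in children if qualifies(c, limit)]
        if len(good) == 1 and good[0] not in maximal:
            maximal.append(good[0])
        else:
            break

    bottom = maximal[-1]
    return bottom if scores[bottom] >= cfg.score_threshold else None
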