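"""Independent brute-force reference implementations used as test oracles.

These re-derive the same quantities as the package by direct enumeration or
by a separately coded transcription of the procedure, and are only meant
for tiny instances.
"""

import itertools
from math import comb

import networkx as nx
import numpy as np


# -- hypergeometric enrichment by exhaustive counting -----------------------

def brute_hypergeom(cluster, geneset, universe):
    """P(overlap >= observed) by summing the hypergeometric pmf directly."""
    M, n, N = len(universe), len(set(geneset) & set(universe)), len(set(cluster) & set(universe))
    observed = len(set(cluster) & set(geneset) & set(universe))
    total = comb(M, N)
    hits = 0
    for k in range(observed, min(n, N) + 1):
        hits += comb(n, k) * comb(M - n, N - k)
    return hits / total


# -- stump reduction by fixpoint chain closure -------------------------------

def brute_reduce_partition(graph):
    """Partition of nodes into stumps, found independently of the package.

    A node is linear when it has at most one parent and at most one child.
    Each linear node's chain is the closure over edges joining linear nodes;
    the chain is then extended at its bottom by a following node having
    several children or none.
    """
    linear = {
        v for v in graph if graph.in_degree(v) <= 1 and graph.out_degree(v) <= 1
    }
    # closure over linear-linear edges
    lg = nx.Graph()
    lg.add_nodes_from(linear)
    for u, v in graph.edges:
        if u in linear and v in linear:
            lg.add_edge(u, v)
    chains = [set(c) for c in nx.connected_components(lg)]
    taken = set()
    stumps = []
    # order chains by their topmost node for deterministic bottom absorption
    order = list(nx.topological_sort(graph))
    pos = {v: i for i, v in enumerate(order)}
    for chain in sorted(chains, key=lambda c: min(pos[v] for v in c)):
        bottom = max(chain, key=lambda v: pos[v])
        stump = set(chain)
        succs = list(graph.successors(bottom))
        if len(succs) == 1:
            nxt = succs[0]
            if graph.out_degree(nxt) != 1 and nxt not in linear and nxt not in taken:
                stump.add(nxt)
        stumps.append(stump)
        taken |= stump
    for v in graph:
        if v not in taken:
            stumps.append({v})
    return {frozenset(s) for s in stumps}


def brute_reduced_edges(graph, node_map):
    return {
        (node_map[u], node_map[v])
        for u, v in graph.edges
        if node_map[u] != node_map[v]
    }


# -- unique enrichment: separately coded transcription ----------------------

def brute_unique_enrichment(graph, adjusted_p, threshold=5.0, slack=5):
    scores = {v: -np.log10(max(adjusted_p[v], 1e-300)) for v in graph}
    order = sorted(graph, key=lambda v: (-scores[v], str(v)))
    rank = {v: i + 1 for i, v in enumerate(order)}
    roots = [v for v in graph if graph.in_degree(v) == 0]
    leaves = [v for v in graph if graph.out_degree(v) == 0]
    paths = []
    for r in roots:
        for l in leaves:
            if r == l:
                paths.append((r,))
            else:
                paths += [tuple(p) for p in nx.all_simple_paths(graph, r, l)]
    if not paths:
        raise ValueError("no root-leaf paths")

    L = [order[0]]
    P = [p for p in paths if order[0] in p]
    if not P:
        return None
    completed = False
    for c in order[1:]:
        P_containing = [p for p in P if c in p]
        if not P_containing:
            break
        if scores[c] < 0.5 * scores[L[-1]] and scores[c] < threshold:
            break
        if any(set(p) <= set(L + [c]) for p in P):
            L, P, completed = L + [c], P_containing, True
            break
        L, P = L + [c], P_containing

    member = set(L)
    if completed or any(set(p) <= member for p in P):
        maximal = list(next(p for p in P if set(p) <= member))
    else:
        after = [c for c in order if c not in member and any(c in p for p in P)]
        if after:
            c = after[0]
            shares_parent = set(graph.predecessors(c)) & set(
                graph.predecessors(L[-1])
            )
            if shares_parent and scores[c] > 0.5 * scores[L[-1]] and scores[c] > threshold:
                L = L[:-1]
                member = set(L)
        if not member:
            return None
        min_score = min(scores[v] for v in member)

        def span(p):
            idx = [i for i, v in enumerate(p) if v in member]
            return list(p[idx[0] : idx[-1] + 1]) if idx else []

        def has_hole(p):
            return any(
                v not in member and scores[v] < min_score for v in span(p)
            )

        if all(has_hole(p) for p in P):
            runs = []
            for p in P:
                cur = []
                for v in p:
                    if v in member:
                        cur.append(v)
                        runs.append(list(cur))
                    else:
                        cur = []
            runs = [r for r in runs if r]
            if not runs:
                return None
            maximal = max(runs, key=lambda r: (len(r), -min(rank[v] for v in r)))
        else:
            maximal = span(next(p for p in P if not has_hole(p)))
    if not maximal:
        return None

    def ok(v, limit):
        return rank[v] < limit and scores[v] >= threshold

    extended = True
    while extended:
        extended = False
        limit = max(rank[v] for v in maximal) + slack
        parents = [p for p in graph.predecessors(maximal[0]) if p not in maximal]
        good = [p for p in parents if ok(p, limit)]
        if len(good) == 1 and len([p for p in graph.predecessors(maximal[0]) if ok(p, limit)]) == 1:
            maximal = [good[0]] + maximal
            extended = True
    extended = True
    while extended:
        extended = False
        limit = max(rank[v] for v in maximal) + slack
        children = [c for c in graph.successors(maximal[-1]) if c not in maximal]
        good = [c for c in children if ok(c, limit)]
        if len(good) == 1 and len([c for c in graph.successors(maximal[-1]) if ok(c, limit)]) == 1:
            maximal = maximal + [good[0]]
            extended = True
    bottom = maximal[-1]
    return bottom if scores[bottom] >= threshold else None


# -- path matching by exhaustive subpath enumeration -------------------------

def all_subpaths(hierarchy):
    subs = set()
    for p in hierarchy.root_leaf_paths():
        for i in range(len(p)):
            for j in range(i + 1, len(p) + 1):
                subs.add(tuple(p[i:j]))
    return subs


def brute_match_pairs(hier_a, hier_b, overlap, frac=0.9):
    """All maximally matched subpath pairs, fully enumerated."""
    subs_a, subs_b = all_subpaths(hier_a), all_subpaths(hier_b)
    matched = set()
    for pa in subs_a:
        for pb in subs_b:
            pairs = [(u, v) for u in pa for v in pb]
            if sum(overlap(u, v) for u, v in pairs) > frac * len(pairs):
                matched.add((pa, pb))

    def contains(big, small):
        m = len(small)
        return any(big[i : i + m] == small for i in range(len(big) - m + 1))

    maximal = set()
    for pa, pb in matched:
        if not any(
            (qa, qb) != (pa, pb) and contains(qa, pa) and contains(qb, pb)
            for qa, qb in matched
        ):
            maximal.add((pa, pb))
    return maximal


# -- cliques and medoids ------------------------------------------------------

def brute_maximal_cliques(n, edges):
    """All maximal cliques of an n-vertex graph by subset enumeration."""
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    cliques = []
    for r in range(1, n + 1):
        for sub in itertools.combinations(range(n), r):
            if all(b in adj[a] for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    return {
        frozenset(c)
        for c in cliques
        if not any(c < other for other in cliques)
    }


def brute_medoid(cooccurrence_mats):
    n = len(cooccurrence_mats)
    totals = []
    for i in range(n):
        totals.append(
            sum(
                np.count_nonzero(cooccurrence_mats[i] != cooccurrence_mats[j])
                for j in range(n)
                if j != i
            )
        )
    return int(np.argmin(totals))
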