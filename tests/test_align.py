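import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from scheter import (
    ClusterOverlap,
    Component,
    MetaCluster,
    SubgraphMatrix,
    align_hierarchies,
    clusters_overlap,
    consensus_meta,
    group_mergeable_paths,
    match_paths,
    merge_components,
    meta_enrichment_score,
    meta_pdiff_ranks,
    nmf_components,
    select_shared_genesets,
    simulate_hierarchy_suite,
    trim_path_tops,
)
from scheter.align import MetaClusterAssignment
from oracles import brute_match_pairs, brute_maximal_cliques, brute_medoid
from test_hierarchy import make_dag, random_level_dag


class TestClustersOverlap:
    def test_identical_sets_overlap(self):
        s = {"a", "b", "c"}
        assert clusters_overlap(s, set(s))

    def test_disjoint_sets_do_not(self):
        assert not clusters_overlap({"a", "b"}, {"c", "d"})

    def test_gray_zone_uses_mutual_top_ten(self, rng):
        # |A| = |B| = 10, overlap 3 -> Jaccard 3/17 ~ 0.176: the verdict
        # depends on the mutual top-ten ranks within two 12-cluster datasets
        universe = [f"g{i}" for i in range(200)]
        a_focus = set(universe[:10])
        b_focus = set(universe[7:17])  # overlap {g7, g8, g9}
        ctx_a = {0: a_focus}
        ctx_b = {0: b_focus}
        for j in range(1, 12):
            ctx_a[j] = set(rng.choice(universe[100:], 8, replace=False))
            ctx_b[j] = set(rng.choice(universe[100:], 8, replace=False))
        assert len(a_focus & b_focus) == 3
        # few competitors share genes with the focus pair, so both rank top
        assert clusters_overlap(a_focus, b_focus, context_a=ctx_a, context_b=ctx_b)
        # bury the pair below ten better partners on each side
        for j in range(1, 12):
            ctx_a[j] = set(universe[7:17]) - {universe[7 + (j % 3)]}
            ctx_b[j] = set(universe[:10]) - {universe[j % 3]}
        oracle = ClusterOverlap(ctx_a, ctx_b)
        ranks_b = np.argsort(-oracle.jaccard[0])  # partner ranks for a_focus
        assert not clusters_overlap(a_focus, b_focus, context_a=ctx_a, context_b=ctx_b)
        assert list(ranks_b).index(0) >= 10  # brute ranking confirms burial

    def test_matrix_matches_pairwise_jaccard(self, rng):
        genes = [f"g{i}" for i in range(40)]
        ca = {i: set(rng.choice(genes, 8, replace=False)) for i in range(5)}
        cb = {j: set(rng.choice(genes, 8, replace=False)) for j in range(5)}
        oracle = ClusterOverlap(ca, cb)
        for i in range(5):
            for j in range(5):
                expected = len(ca[i] & cb[j]) / len(ca[i] | cb[j])
                assert oracle.jaccard[i, j] == pytest.approx(expected)


def hierarchy_with_genes(edges, gene_map, levels=None):
    return make_dag(edges, levels=levels, genes=gene_map)


def linear_hierarchy(tag, gene_map):
    nodes = list(gene_map)
    edges = list(zip(nodes, nodes[1:]))
    levels = {v: i + 1 for i, v in enumerate(nodes)}
    return hierarchy_with_genes(edges, gene_map, levels)


class TestMatchPaths:
    def test_overlapping_middle_clusters_match_maximally(self):
        # clusters 2-4 and 2'-4' mutually overlap (shared core); the tops
        # overlap each other but not the middles, and the bottoms nothing
        core = {f"m{j}" for j in range(20)}
        top = {f"top_{j}" for j in range(10)}
        ga = {
            "n1": set(top),
            "n2": core | {"a2"},
            "n3": core | {"a3"},
            "n4": core | {"a4"},
            "n5": {f"b5_{j}" for j in range(10)},
        }
        gb = {
            "n1p": set(top),
            "n2p": core | {"p2"},
            "n3p": core | {"p3"},
            "n4p": core | {"p4"},
            "n5p": {f"c5_{j}" for j in range(10)},
        }
        ha = linear_hierarchy("a", ga)
        hb = linear_hierarchy("b", gb)
        oracle = ClusterOverlap(
            {v: ha.genes_of(v) for v in ha.graph}, {v: hb.genes_of(v) for v in hb.graph}
        )
        matches = match_paths(ha, hb, oracle)
        found = {(m.path_a, m.path_b) for m in matches}
        # despite the overlapping top pair, the maximal match is the middle
        assert (("n2", "n3", "n4"), ("n2p", "n3p", "n4p")) in found
        assert (("n1", "n2", "n3", "n4"), ("n1p", "n2p", "n3p", "n4p")) not in found

    def test_identical_hierarchies_self_match_full_paths(self):
        # nested clusters keep every cross pair overlapping along the path
        base = [f"x{j}" for j in range(12)]
        gene_map = {f"n{i}": set(base[: 12 - i]) for i in range(1, 5)}
        h = linear_hierarchy("a", gene_map)
        clusters = {v: h.genes_of(v) for v in h.graph}
        oracle = ClusterOverlap(clusters, clusters)
        matches = match_paths(h, h, oracle)
        full = tuple(f"n{i}" for i in range(1, 5))
        assert any(m.path_a == full and m.path_b == full for m in matches)

    def test_matches_brute_force_on_random_instances(self, rng):
        genes = [f"g{i}" for i in range(30)]
        for seed in range(12):
            ha = random_level_dag(seed, max_nodes=8)
            hb = random_level_dag(100 + seed, max_nodes=8)
            r = np.random.default_rng(seed)
            for h in (ha, hb):
                for v in h.graph:
                    h.graph.nodes[v]["genes"] = frozenset(
                        r.choice(genes, 6, replace=False)
                    )
            oracle = ClusterOverlap(
                {v: ha.genes_of(v) for v in ha.graph},
                {v: hb.genes_of(v) for v in hb.graph},
            )
            ours = {
                (m.path_a, m.path_b)
                for m in match_paths(ha, hb, oracle)
            }
            ref = brute_match_pairs(ha, hb, oracle.overlap)
            assert ours == ref


class TestTrimPathTops:
    def test_shared_root_with_disjoint_branches_is_trimmed(self):
        # dataset A: a root of all genes splitting into two disjoint halves;
        # dataset B matches the root plus one half.  The root is shared with
        # a complementary branch that is unrelated to the matched portion,
        # so the top node is dropped from the matched path.
        root = {f"r{j}" for j in range(30)}
        b2 = set(sorted(root)[:15])
        b3 = root - b2
        ha = hierarchy_with_genes(
            [("n1", "n2"), ("n1", "n3")],
            {"n1": root, "n2": b2, "n3": b3},
            {"n1": 1, "n2": 2, "n3": 2},
        )
        hb = hierarchy_with_genes(
            [("m1", "m2")],
            {"m1": set(root), "m2": set(b2)},
            {"m1": 1, "m2": 2},
        )
        oracle = ClusterOverlap(
            {v: ha.genes_of(v) for v in ha.graph},
            {v: hb.genes_of(v) for v in hb.graph},
        )
        matches = match_paths(ha, hb, oracle)
        assert any(m.path_a == ("n1", "n2") for m in matches)
        trimmed = trim_path_tops(matches, ha, hb, oracle)
        paths_a = {m.path_a for m in trimmed}
        assert ("n1", "n2") not in paths_a
        assert ("n2",) in paths_a

    def test_without_shared_tops_matches_unchanged(self, rng):
        gene_map = {f"n{i}": {f"x{i}_{j}" for j in range(6)} for i in range(1, 4)}
        h = linear_hierarchy("a", gene_map)
        clusters = {v: h.genes_of(v) for v in h.graph}
        oracle = ClusterOverlap(clusters, clusters)
        matches = match_paths(h, h, oracle)
        assert trim_path_tops(list(matches), h, h, oracle) == matches


class TestGroupMergeablePaths:
    def _two_dataset_setup(self):
        # dataset 0: two paths sharing the top, both matching the single
        # dataset-1 path -> mergeable into one subgraph
        top = {f"t{j}" for j in range(24)}
        left = set(sorted(top)[:12])
        right = set(sorted(top)[:11]) | {"r_extra"}  # heavy overlap with left
        ha = hierarchy_with_genes(
            [("a_top", "a_left"), ("a_top", "a_right")],
            {"a_top": top, "a_left": left, "a_right": right},
            {"a_top": 1, "a_left": 2, "a_right": 2},
        )
        hb = hierarchy_with_genes(
            [("b_top", "b_mid")],
            {"b_top": set(top), "b_mid": set(left)},
            {"b_top": 1, "b_mid": 2},
        )
        return ha, hb

    def test_same_top_paths_with_overlapping_matches_merge(self):
        ha, hb = self._two_dataset_setup()
        oracle = ClusterOverlap(
            {v: ha.genes_of(v) for v in ha.graph},
            {v: hb.genes_of(v) for v in hb.graph},
        )
        matches = {(0, 1): match_paths(ha, hb, oracle)}
        paths_a = {m.path_a for m in matches[(0, 1)]}
        assert ("a_top", "a_left") in paths_a and ("a_top", "a_right") in paths_a
        subgraphs = group_mergeable_paths(matches, [ha, hb])
        A0 = subgraphs[0]
        merged_rows = [
            nodes
            for nodes in A0.subgraph_nodes
            if {"a_top", "a_left", "a_right"} <= set(nodes)
        ]
        assert merged_rows  # both paths landed in one subgraph

    def test_non_mergeable_paths_stay_separate(self):
        # distinct tops -> never mergeable -> one subgraph per matched path
        g1 = {f"p{j}" for j in range(8)}
        g2 = {f"q{j}" for j in range(8)}
        ha = hierarchy_with_genes(
            [("a1", "a2"), ("b1", "b2")],
            {"a1": g1, "a2": g2, "b1": {f"z{j}" for j in range(8)}, "b2": {f"y{j}" for j in range(8)}},
            {"a1": 1, "a2": 2, "b1": 1, "b2": 2},
        )
        hb = hierarchy_with_genes(
            [("c1", "c2")], {"c1": g1, "c2": g2}, {"c1": 1, "c2": 2}
        )
        oracle = ClusterOverlap(
            {v: ha.genes_of(v) for v in ha.graph},
            {v: hb.genes_of(v) for v in hb.graph},
        )
        matches = {(0, 1): match_paths(ha, hb, oracle)}
        subgraphs = group_mergeable_paths(matches, [ha, hb])
        assert all(row.sum() >= 1 for row in subgraphs[0].matrix)

    def test_cliques_match_exhaustive_search(self, rng):
        # random mergeability graph resolved through the same clique step
        n = 7
        edges = [
            (i, j)
            for i, j in itertools.combinations(range(n), 2)
            if rng.random() < 0.4
        ]
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        ours = {frozenset(c) for c in nx.find_cliques(g)}
        assert ours == brute_maximal_cliques(n, edges)


def two_component_toy_matrix():
    """Four subgraphs over eight edges built from two overlapping components."""
    edges = [(1, 2), (2, 3), (3, 4), (3, 5), (5, 6), (5, 7), (7, 8), (8, 9)]
    e = {i + 1: edges[i] for i in range(8)}
    comp1 = [e[1], e[2], e[4]]          # {e1, e2, e4}
    comp2 = [e[1], e[2], e[3]]          # {e1, e2, e3}
    rows = []
    for combo in (comp1, comp2, comp1 + comp2, comp1):
        row = np.array([1 if ed in combo else 0 for ed in edges])
        rows.append(row)
    return SubgraphMatrix(0, edges, np.array(rows), [frozenset()] * 4), e


class TestNmfComponents:
    def test_two_component_toy_recovers_both(self):
        A, e = two_component_toy_matrix()
        hits = 0
        for seed in range(10):
            comps = nmf_components(A, k_range=[2], seed=seed)
            found = {c.edges for c in comps}
            if frozenset({e[1], e[2], e[4]}) in found and frozenset(
                {e[1], e[2], e[3]}
            ) in found:
                hits += 1
        assert hits >= 5

    def test_single_row_matrix_yields_its_edge_set(self):
        edges = [(1, 2), (2, 3), (3, 4)]
        A = SubgraphMatrix(0, edges, np.array([[1, 1, 1]]), [frozenset({1, 2, 3, 4})])
        comps = nmf_components(A, k_range=[2], seed=0)
        assert {c.edges for c in comps} <= {frozenset(edges)}

    def test_rank_one_matrix_gives_single_component(self):
        edges = [(1, 2), (2, 3), (3, 4)]
        A = SubgraphMatrix(
            0, edges, np.tile([1, 1, 0], (3, 1)), [frozenset()] * 3
        )
        comps = nmf_components(A, k_range=[2, 3], seed=1)
        assert {c.edges for c in comps} == {frozenset({(1, 2), (2, 3)})}

    def test_disconnected_component_discarded(self):
        edges = [(1, 2), (3, 4)]
        A = SubgraphMatrix(0, edges, np.array([[1, 1]]), [frozenset()])
        assert nmf_components(A, k_range=[1], seed=0) == []


class TestMergeComponents:
    def _hier(self):
        gene_map = {
            f"n{i}": {f"g{i}_{j}" for j in range(5)} for i in range(1, 5)
        }
        return linear_hierarchy("a", gene_map)

    def test_identical_components_merge(self):
        h = self._hier()
        c1 = Component(0, frozenset({("n1", "n2"), ("n2", "n3")}))
        c2 = Component(0, frozenset({("n1", "n2"), ("n2", "n3")}))
        metas = merge_components([c1, c2], [h])
        assert len(metas) == 1
        assert metas[0].clusters == frozenset({(0, "n1"), (0, "n2"), (0, "n3")})

    def test_disjoint_components_stay_separate(self):
        h = self._hier()
        c1 = Component(0, frozenset({("n1", "n2")}))
        c2 = Component(0, frozenset({("n3", "n4")}))
        metas = merge_components([c1, c2], [h])
        assert len(metas) == 2

    def test_cross_dataset_merge_through_shared_genes(self):
        shared = {f"s{j}" for j in range(10)}
        ha = linear_hierarchy("a", {"a1": shared | {"extra_a"}, "a2": set(shared)})
        hb = linear_hierarchy("b", {"b1": set(shared), "b2": shared | {"extra_b"}})
        ca = Component(0, frozenset({("a1", "a2")}))
        cb = Component(1, frozenset({("b1", "b2")}))
        metas = merge_components([ca, cb], [ha, hb])
        assert len(metas) == 1
        assert {d for d, _ in metas[0].clusters} == {0, 1}


def meta(clusters):
    return MetaCluster((), frozenset((0, c) for c in clusters))


class TestConsensusMeta:
    def test_five_trial_toy_picks_the_central_trial(self):
        # trials 1-4 each deviate from the reference partition in a
        # different direction; the reference trial (index 4) is the medoid
        reference = [meta({1, 2, 3, 4, 5}), meta({6, 7, 8, 9, 10})]
        trials = [
            [meta({1, 2, 3, 4, 5, 6}), meta({7, 8, 9, 10})],
            [meta({1, 2, 3, 4}), meta({5, 6, 7, 8, 9, 10})],
            [meta({1, 2, 3, 4, 5, 7}), meta({6, 8, 9, 10})],
            [meta({1, 2, 3, 4, 5}), meta({6, 7, 8, 9})],
            reference,
        ]
        out = consensus_meta(trials)
        assert out.trial_id == 4
        assert out.meta_clusters[1].clusters == reference[0].clusters

    def test_identical_trials_distance_zero(self):
        trials = [[meta({1, 2}), meta({3, 4})]] * 3
        out = consensus_meta(trials)
        assert out.trial_id == 0

    def test_medoid_matches_brute_force(self, rng):
        universe = [(0, c) for c in range(6)]
        trials = []
        for _ in range(3):
            k = int(rng.integers(1, 3))
            labels = rng.integers(0, k + 1, size=6)
            trials.append(
                [
                    MetaCluster((), frozenset((0, c) for c in np.flatnonzero(labels == l)))
                    for l in range(k + 1)
                    if (labels == l).any()
                ]
            )
        from scheter.align import _cooccurrence

        mats = [_cooccurrence(t, universe) for t in trials]
        assert consensus_meta(trials, universe=universe).trial_id == brute_medoid(mats)

    def test_merge_map_combines_meta_clusters(self):
        trials = [[meta({1, 2}), meta({3, 4})]]
        out = consensus_meta(trials, merge_map={2: 1})
        assert len(out.meta_clusters) == 1
        assert out.meta_clusters[1].clusters == frozenset(
            (0, c) for c in (1, 2, 3, 4)
        )

    def test_assignments_and_orphans_partition_universe(self):
        universe = [(0, c) for c in range(8)]
        trials = [[meta({1, 2}), meta({2, 3})]]
        out = consensus_meta(trials, universe=universe)
        covered = {c for c, ids in out.assignments.items() if ids}
        assert covered | out.orphans() == set(universe)
        assert out.assignments[(0, 2)] == {1, 2}  # many-to-many membership


class TestMetaCharacterization:
    def _assignment(self, h):
        clusters = frozenset({(0, "n1"), (0, "n2"), (0, "n3")})
        mc = MetaCluster((), clusters)
        universe = frozenset((0, v) for v in h.graph.nodes)
        return MetaClusterAssignment(
            {c: ({1} if c in clusters else set()) for c in universe},
            {1: mc},
            0,
            universe,
        )

    def test_equal_scores_along_one_path_give_that_score(self):
        gene_map = {f"n{i}": {f"g{i}"} for i in range(1, 5)}
        h = linear_hierarchy("a", gene_map)
        assignment = self._assignment(h)
        p = {v: 1e-8 for v in h.graph.nodes}
        score = meta_enrichment_score(assignment, 1, 0, h, p)
        assert score == pytest.approx(8.0)

    def test_no_qualifying_path_gives_none(self):
        gene_map = {f"n{i}": {f"g{i}"} for i in range(1, 5)}
        h = linear_hierarchy("a", gene_map)
        assignment = self._assignment(h)
        p = {v: 0.5 for v in h.graph.nodes}
        assert meta_enrichment_score(assignment, 1, 0, h, p) is None

    def test_geometric_mean_over_union_of_qualifying_paths(self):
        # diamond: n1 -> n2a/n2b -> n3; two maximal 3-node paths
        h = hierarchy_with_genes(
            [("n1", "n2a"), ("n1", "n2b"), ("n2a", "n3"), ("n2b", "n3")],
            {"n1": {"g1"}, "n2a": {"g2"}, "n2b": {"g3"}, "n3": {"g4"}},
            {"n1": 1, "n2a": 2, "n2b": 2, "n3": 3},
        )
        clusters = frozenset((0, v) for v in h.graph.nodes)
        assignment = MetaClusterAssignment(
            {c: {1} for c in clusters}, {1: MetaCluster((), clusters)}, 0, clusters
        )
        p = {"n1": 1e-4, "n2a": 1e-6, "n2b": 1e-8, "n3": 1e-10}
        expected = np.exp(np.mean(np.log([4, 6, 8, 10])))
        score = meta_enrichment_score(assignment, 1, 0, h, p)
        assert score == pytest.approx(expected)

    def test_pdiff_rank_averaging(self):
        h = linear_hierarchy("a", {f"n{i}": {f"g{i}"} for i in range(1, 4)})
        assignment = self._assignment(h)
        ranks = {0: {"n1": 1.0, "n2": 3.0, "n3": 2.0}}
        out = meta_pdiff_ranks(assignment, ranks)
        assert out[1] == pytest.approx(2.0)

    def test_select_shared_genesets_needs_two_datasets(self):
        idx = pd.MultiIndex.from_product([[1, 2], [0, 1, 2]])
        scores = pd.DataFrame(1.0, index=idx, columns=["S1", "S2", "S3"])
        scores.loc[(1, 0), "S1"] = 1e-4
        scores.loc[(1, 1), "S1"] = 1e-5
        scores.loc[(2, 2), "S2"] = 1e-6  # one dataset only
        out = select_shared_genesets(scores)
        assert list(out.index) == ["S1"]
        grouped = select_shared_genesets(scores, focal=(1, 2))
        assert grouped.loc["S1", "group"] == 1


class TestEndToEnd:
    def test_planted_shared_blocks_become_meta_clusters(self):
        from scheter import build_full_hierarchy, reduce_hierarchy

        suite = simulate_hierarchy_suite(
            n_datasets=2, n_genes=120, n_shared_blocks=1, n_private_blocks=1,
            block_size=30, n_cells=50, seed=5,
        )
        reduced = []
        for m in suite.datasets:
            full = build_full_hierarchy(m, k_max=4, n_runs=25, seed=1)
            reduced.append(reduce_hierarchy(full))
        assignment = align_hierarchies(reduced, n_trials=5, k_range=[2, 3], seed=2)
        assert assignment.universe
        covered = {c for c, ids in assignment.assignments.items() if ids}
        assert covered | assignment.orphans() == set(assignment.universe)
        if assignment.meta_clusters:
            shared = next(iter(suite.shared_blocks().values()))
            jaccards = []
            for mid, mc in assignment.meta_clusters.items():
                genes = mc.genes(reduced)
                jaccards.append(len(genes & shared) / len(genes | shared))
            assert max(jaccards) > 0.2
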