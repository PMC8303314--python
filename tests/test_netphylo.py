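"""Character coding, step distances, NJ trees and median-joining networks."""

import io
import itertools

import networkx as nx
import numpy as np
import pytest
from skbio.tree import TreeNode

from beemito.netphylo import (
    Character,
    CharacterMatrix,
    distance_frame,
    encode_characters,
    median_joining_network,
    nj_bootstrap_tree,
    nj_tree,
    step_distance,
)


def binary_matrix(vectors: dict[str, str]) -> CharacterMatrix:
    taxa = list(vectors)
    length = len(next(iter(vectors.values())))
    chars = [Character(f"c{i}", "P", 1,
                       tuple(vectors[t][i] for t in taxa))
             for i in range(length)]
    return CharacterMatrix(taxa=taxa, characters=chars)


class TestEncoding:
    def test_identical_taxa_share_all_states(self, catalog):
        m = encode_characters(catalog, include_outgroup=False)
        # A4p and A4q differ only by the published 298 insertion
        assert step_distance(m, "A4p", "A4q") == 1

    def test_a1_vs_a1t_three_characters(self, catalog):
        m = encode_characters(catalog, include_outgroup=False)
        ia, ib = m.taxa.index("A1"), m.taxa.index("A1t")
        differing = [c.cid for c in m.characters
                     if "?" not in (c.states[ia], c.states[ib])
                     and c.states[ia] != c.states[ib]]
        assert sorted(differing) == ["col139", "col646", "col99"]

    def test_m7b_vs_m7c_single_step(self, catalog):
        m = encode_characters(catalog, include_outgroup=False)
        assert step_distance(m, "M7b", "M7c") == 1

    def test_self_distance_zero_and_symmetry(self, catalog):
        m = encode_characters(catalog, include_outgroup=False)
        assert step_distance(m, "A4p", "A4p") == 0
        assert (step_distance(m, "A1", "C2")
                == step_distance(m, "C2", "A1"))

    def test_unknown_taxon_rejected(self, catalog):
        m = encode_characters(catalog, include_outgroup=False)
        with pytest.raises(KeyError):
            step_distance(m, "A1", "nope")

    def test_all_observed_haplotypes_distinct(self, catalog):
        m = encode_characters(catalog, include_outgroup=False)
        d = distance_frame(m)
        observed = [r.name for r in catalog.records if r.observed]
        for a, b in itertools.combinations(observed, 2):
            assert d.loc[a, b] > 0, f"{a} and {b} are not separated"

    def test_triangle_inequality_on_complete_data_taxa(self, catalog):
        """The weighted step distance is a metric wherever no states are
        missing; only element-absent taxa (coded missing across a whole
        element, e.g. the Q-less A65) can break the triangle inequality."""
        m = encode_characters(catalog, include_outgroup=True)
        d = distance_frame(m)
        complete = [t for i, t in enumerate(m.taxa)
                    if all(ch.states[i] != "?" for ch in m.characters)]
        assert len(complete) >= 5
        for a, b, c in itertools.permutations(complete, 3):
            assert d.loc[a, b] <= d.loc[a, c] + d.loc[c, b] + 1e-9
        # violations, where present, always route through element-absent taxa
        incomplete = set(m.taxa) - set(complete)
        for a, b, c in itertools.permutations(m.taxa, 3):
            if d.loc[a, b] > d.loc[a, c] + d.loc[c, b] + 1e-9:
                assert c in incomplete

    def test_no_polymorphic_column_lost(self, catalog):
        """Column accounting: outside the DraI site windows, a column is a
        per-column character exactly when the taxa that structurally carry
        the element disagree there; no polymorphism is silently dropped and
        no monomorphic column is kept."""
        from beemito import grammar
        m = encode_characters(catalog, include_outgroup=False)
        covered = {int(c.cid[3:]) for c in m.characters
                   if c.cid.startswith("col")}
        drai = {c for cols in grammar.DRAI_WINDOW_COLUMNS.values()
                for c in cols}
        regions = [("P", grammar.P_COLS), ("Q1", grammar.Q1_COLS),
                   ("Q2", grammar.Q2_COLS), ("cox2", grammar.COX2_COLS)]
        for region, (lo, hi) in regions:
            for col in range(lo, hi + 1):
                if col in drai:
                    assert col not in covered
                    continue
                states = set()
                for rec in catalog.records:
                    if region == "P" and (
                            rec.pattern[:1] != "P"
                            or col in grammar.p_form_deleted_columns(
                                rec.pattern[:2] if rec.pattern[:2] in
                                ("P0", "P1") else "P")):
                        continue
                    if region == "Q1" and rec.pattern.count("Q") < 1:
                        continue
                    if region == "Q2" and rec.pattern.count("Q") < 2:
                        continue
                    states.add(catalog.aligned(rec.name)[col - 1])
                assert (col in covered) == (len(states) >= 2), \
                    f"column {col} mis-coded"


class TestNJTree:
    def test_additive_four_taxon_case(self):
        # distances from the tree ((a:1,b:2):1,(c:3,d:4):1)
        from skbio import DistanceMatrix
        from skbio.tree import nj
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                     dtype=float)
        tree = nj(DistanceMatrix(d, list("abcd")))
        parts = {frozenset(t.name for t in n.tips())
                 for n in tree.non_tips(include_self=False)}
        assert frozenset({"a", "b"}) in parts or frozenset({"c", "d"}) in parts

    def test_random_topologies_recovered(self):
        """NJ on additive distances from random 8-taxon trees with positive
        branch lengths recovers the generating topology."""
        recovered = 0
        reps = 30
        for seed in range(reps):
            dist, parts = _random_tree_distances(8, seed)
            from skbio import DistanceMatrix
            from skbio.tree import nj
            tree = nj(DistanceMatrix(dist, [f"t{i}" for i in range(8)]))
            got = _tree_bipartitions(tree)
            recovered += got == parts
        assert recovered == reps

    def test_c_lineage_cluster_in_rooted_tree(self, catalog):
        m = encode_characters(catalog, include_outgroup=True)
        newick = nj_bootstrap_tree(m, n_bootstrap=50, seed=2,
                                   outgroup=catalog.outgroup_name)
        tree = TreeNode.read(io.StringIO(newick))
        c_taxa = {r.name for r in catalog.records if r.lineage == "C"}
        clades = [{t.name for t in n.tips()} for n in tree.non_tips()]
        assert c_taxa in clades, "C haplotypes are not monophyletic"

    def test_bootstrap_deterministic_under_seed(self, catalog):
        m = encode_characters(catalog, include_outgroup=True)
        a = nj_bootstrap_tree(m, n_bootstrap=25, seed=9,
                              outgroup=catalog.outgroup_name)
        b = nj_bootstrap_tree(m, n_bootstrap=25, seed=9,
                              outgroup=catalog.outgroup_name)
        assert a == b

    def test_too_few_taxa_rejected(self):
        m = binary_matrix({"a": "01", "b": "10", "c": "11"})
        with pytest.raises(ValueError):
            nj_bootstrap_tree(m, n_bootstrap=0, seed=0)


class TestMedianJoining:
    def test_two_haplotypes_single_edge(self):
        m = binary_matrix({"h1": "000", "h2": "111"})
        net = median_joining_network(m)
        assert net.edges == [("h1", "h2", 3)]
        assert all(a["kind"] == "observed" for a in net.nodes.values())

    def test_three_taxon_star_median(self):
        """Three haplotypes at pairwise distance 2 gain one median node
        (the coordinate-wise majority vector, the optimal Steiner point)
        giving total length 3 < the 4-step spanning path."""
        m = binary_matrix({"x": "110", "y": "011", "z": "101"})
        net = median_joining_network(m)
        medians = [n for n, a in net.nodes.items() if a["kind"] == "median"]
        assert len(medians) == 1
        (mv,) = medians
        assert net.nodes[mv]["states"] == ("1", "1", "1")  # brute-force optimum
        assert sorted(net.edges) == sorted(
            [("x", mv, 1), ("y", mv, 1), ("z", mv, 1)])
        assert sum(w for _, _, w in net.edges) == 3

    def test_star_median_matches_brute_force_steiner(self):
        """Exhaustive check over all 8 binary vectors: the majority vector
        uniquely minimises the total star length for the 3-taxon case."""
        vecs = {"x": "110", "y": "011", "z": "101"}
        best = min(("".join(b) for b in itertools.product("01", repeat=3)),
                   key=lambda v: sum(sum(a != b for a, b in zip(v, w))
                                     for w in vecs.values()))
        assert best == "111"

    def test_mst_containment_on_random_binary_instances(self):
        """At epsilon=0 the network contains a minimum spanning tree of its
        final node set (the MSN is the union of all MSTs)."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            vectors = {f"t{i}": "".join(rng.choice(list("01"), 10))
                       for i in range(8)}
            if len(set(vectors.values())) < 8:
                continue
            m = binary_matrix(vectors)
            net = median_joining_network(m)
            states = {n: net.nodes[n]["states"] for n in net.nodes}
            g = nx.Graph()
            for u, v in itertools.combinations(states, 2):
                w = sum(a != b for a, b in zip(states[u], states[v]))
                g.add_edge(u, v, weight=w)
            mst = nx.minimum_spanning_tree(g)
            net_edges = {frozenset((u, v)) for u, v, _ in net.edges}
            for u, v in mst.edges:
                assert frozenset((u, v)) in net_edges
            assert nx.is_connected(
                nx.Graph([(u, v) for u, v, _ in net.edges]))

    def test_median_pruning_fixpoint(self, catalog):
        """Every median vector in the final network has degree >= 3."""
        m = encode_characters(catalog, include_outgroup=False)
        net = median_joining_network(m)
        for name, attrs in net.nodes.items():
            if attrs["kind"] == "median":
                assert net.degree(name) >= 3

    def test_lineage_clusters_separated_by_upweighted_characters(self, catalog):
        """In the observed-haplotype minimum spanning network the three
        lineage clusters connect only through upweighted structural steps:
        every inter-lineage link outweighs every intra-lineage link."""
        from beemito.netphylo import _minimum_spanning_network
        m = encode_characters(catalog, include_outgroup=False)
        d = distance_frame(m)
        names = list(m.taxa)
        dist = {(a, b): int(d.loc[a, b]) for a in names for b in names
                if a != b}
        msn = _minimum_spanning_network(names, dist, 0)
        lineage = {r.name: r.lineage for r in catalog.records}
        intra = [w for u, v, w in msn if lineage[u] == lineage[v]]
        inter = [w for u, v, w in msn if lineage[u] != lineage[v]]
        assert inter, "clusters should be linked"
        assert max(intra) < min(inter)
        assert max(inter) > max(intra)


def _random_tree_distances(n_taxa: int, seed: int):
    """Additive tip distances from a random binary tree with positive branch
    lengths, plus its non-trivial bipartitions (the recovery target)."""
    rng = np.random.default_rng(seed)
    nodes = [(f"t{i}",) for i in range(n_taxa)]
    g = nx.Graph()
    counter = itertools.count()
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = (f"n{next(counter)}",)
        g.add_edge(a, parent, weight=float(rng.uniform(0.5, 2.0)))
        g.add_edge(b, parent, weight=float(rng.uniform(0.5, 2.0)))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    tips = [(f"t{i}",) for i in range(n_taxa)]
    dist = np.zeros((n_taxa, n_taxa))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i, j in itertools.combinations(range(n_taxa), 2):
        dist[i, j] = dist[j, i] = lengths[tips[i]][tips[j]]
    # bipartitions: remove each internal edge
    parts = set()
    tip_set = frozenset(f"t{i}" for i in range(n_taxa))
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        comp = frozenset(x[0] for x in nx.node_connected_component(h, u)
                         if x[0].startswith("t"))
        if 1 < len(comp) < n_taxa - 1:
            parts.add(min(comp, tip_set - comp,
                          key=lambda s: (len(s), sorted(s))))
    return dist, parts


def _tree_bipartitions(tree):
    tips = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            parts.add(min(side, tips - side, key=lambda s: (len(s), sorted(s))))
    return parts
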