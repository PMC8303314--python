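"""Character coding, mutational-step distances, NJ phylogeny and the
median-joining haplotype network.

Haplotypes are coded as weighted categorical characters derived from the
catalog master alignment: per-column characters for the polymorphic sites of
the P element, the Q copies and the cox2 fragment (gaps are a fifth state),
plus binary indicator characters for structural events — the large P-element
deletions and the absence of P or Q elements — and for the two diagnostic
DraI restriction sites.  Structural indicators and the two DraI characters
are upweighted (default weight 10); element absence indicators count a single
mutational step, and the columns an absent element would occupy are coded as
missing data.

Distances between haplotypes are weighted counts of differing characters with
missing states skipped.  The phylogeny is neighbor joining with character
bootstrap; the network is a Bandelt-style median-joining network (minimum
spanning network plus median vectors from triplets, with obsolete median
pruning).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from . import grammar
from .refdata import HaplotypeCatalog

MISSING = "?"
GAP = "-"

#: default weight for large-deletion indicators and DraI-site characters
UPWEIGHT = 10


@dataclass(frozen=True)
class Character:
    cid: str                      # e.g. "col99", "ind:P_absent", "drai:trna"
    provenance: str               # "P" | "Q1" | "Q2" | "cox2" | "indicator"
    weight: int
    states: tuple[str, ...]       # one state per taxon, in matrix taxon order


@dataclass
class CharacterMatrix:
    taxa: list[str]
    characters: list[Character]

    def state_of(self, cid: str, taxon: str) -> str:
        i = self.taxa.index(taxon)
        for ch in self.characters:
            if ch.cid == cid:
                return ch.states[i]
        raise KeyError(cid)

    def to_frame(self) -> pd.DataFrame:
        data = {ch.cid: list(ch.states) for ch in self.characters}
        df = pd.DataFrame(data, index=self.taxa)
        return df


@dataclass
class HaploNetwork:
    """Median-joining network: observed haplotypes plus median vectors."""

    nodes: dict[str, dict]        # name -> {"kind": observed|median, ...}
    edges: list[tuple[str, str, int]]   # (u, v, mutational steps >= 1)
    connected: bool = True

    def degree(self, name: str) -> int:
        return sum(name in (u, v) for u, v, _ in self.edges)

    def neighbors(self, name: str):
        for u, v, w in self.edges:
            if u == name:
                yield v, w
            elif v == name:
                yield u, w


# ---------------------------------------------------------------------------
# Character encoding
# ---------------------------------------------------------------------------

def _pattern_q_count(pattern: str) -> int:
    return pattern.count("Q")


def _pattern_p_form(pattern: str) -> str:
    head = pattern[:2]
    if head in ("P0", "P1"):
        return head
    if pattern.startswith("P"):
        return "P"
    return "absent"


def encode_characters(catalog: HaplotypeCatalog, include_outgroup: bool = True,
                      upweight: int = UPWEIGHT) -> CharacterMatrix:
    """Build the weighted character matrix from the catalog alignment.

    Columns occupied by a structurally absent element (missing P, missing Q
    copies) are coded as missing data for the affected taxa and the events
    themselves enter as binary indicator characters: a single step for
    element absences, upweighted steps for the large P deletions.  The two
    diagnostic DraI site configurations (tRNAleu 3' end, first-Q 5' end)
    are separate upweighted presence/absence characters; their sequence
    windows are excluded from per-column coding so the restriction sites are
    not double-counted.  Monomorphic characters are dropped.
    """
    taxa = [r.name for r in catalog.records]
    rows = {name: catalog.aligned(name) for name in taxa}
    p_forms = {r.name: _pattern_p_form(r.pattern) for r in catalog.records}
    q_counts = {r.name: _pattern_q_count(r.pattern) for r in catalog.records}
    if include_outgroup:
        og = catalog.outgroup_name
        taxa = taxa + [og]
        rows[og] = catalog.outgroup_row
        p_forms[og] = "P0"
        q_counts[og] = 0

    drai_cols = {c for cols in grammar.DRAI_WINDOW_COLUMNS.values() for c in cols}

    def missing_cols(name: str) -> set[int]:
        cols: set[int] = set()
        cols |= grammar.p_form_deleted_columns(p_forms[name])
        if q_counts[name] < 1:
            cols |= set(grammar.Q1_BASE_COLUMNS) | set(range(*grammar.Q1_COLS))
        if q_counts[name] < 2:
            cols |= set(grammar.Q2_BASE_COLUMNS) | set(range(*grammar.Q2_COLS))
        return cols

    miss = {name: missing_cols(name) for name in taxa}

    characters: list[Character] = []

    def add(cid, provenance, weight, states):
        observed = {s for s in states if s != MISSING}
        if len(observed) >= 2:
            characters.append(Character(cid, provenance, weight, tuple(states)))

    # per-column characters over P, Q1, Q2 and cox2
    regions = (("P", range(grammar.P_COLS[0], grammar.P_COLS[1] + 1)),
               ("Q1", range(grammar.Q1_COLS[0], grammar.Q1_COLS[1] + 1)),
               ("Q2", range(grammar.Q2_COLS[0], grammar.Q2_COLS[1] + 1)),
               ("cox2", range(grammar.COX2_COLS[0], grammar.COX2_COLS[1] + 1)))
    for provenance, cols in regions:
        for col in cols:
            if col in drai_cols:
                continue
            states = [MISSING if col in miss[t] else rows[t][col - 1]
                      for t in taxa]
            add(f"col{col}", provenance, 1, states)

    # structural indicators
    add("ind:P_absent", "indicator", upweight,
        ["1" if p_forms[t] == "absent" else "0" for t in taxa])
    add("ind:P_middle_deletion", "indicator", upweight,
        [MISSING if p_forms[t] == "absent" else
         ("1" if p_forms[t] == "P" else "0") for t in taxa])
    add("ind:P_3prime_deletion", "indicator", upweight,
        [MISSING if p_forms[t] == "absent" else
         ("1" if p_forms[t] == "P1" else "0") for t in taxa])
    add("ind:first_Q_absent", "indicator", 1,
        ["1" if q_counts[t] < 1 else "0" for t in taxa])
    add("ind:second_Q", "indicator", 1,
        ["1" if q_counts[t] >= 2 else "0" for t in taxa])

    # DraI restriction-site characters (presence of the planted motif)
    def window_state(t: str, window: str) -> str:
        cols = grammar.DRAI_WINDOW_COLUMNS[window]
        if any(c in miss[t] for c in cols):
            return MISSING
        text = "".join(rows[t][c - 1] for c in cols)
        return "1" if text == grammar.DRAI_MOTIF else "0"

    add("drai:trna", "indicator", upweight,
        [window_state(t, "trna") for t in taxa])
    add("drai:q1_5prime", "indicator", upweight,
        [window_state(t, "q5") for t in taxa])
    add("drai:q1_middle", "indicator", 1,
        [window_state(t, "qmid") for t in taxa])

    return CharacterMatrix(taxa=taxa, characters=characters)


def write_character_matrix(matrix: CharacterMatrix, path) -> None:
    """Dump the matrix as TSV for inspection: one taxon per row, one
    character per column, with weight and provenance header rows."""
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(c.cid for c in matrix.characters) + "\n")
        fh.write("#weight\t" + "\t".join(str(c.weight) for c in matrix.characters) + "\n")
        fh.write("#provenance\t" + "\t".join(c.provenance for c in matrix.characters) + "\n")
        for i, taxon in enumerate(matrix.taxa):
            fh.write(taxon + "\t" +
                     "\t".join(c.states[i] for c in matrix.characters) + "\n")


# ---------------------------------------------------------------------------
# Step distances
# ---------------------------------------------------------------------------

def step_distance(matrix: CharacterMatrix, taxon_a: str, taxon_b: str) -> int:
    """Weighted count of differing characters (missing states skipped)."""
    try:
        ia, ib = matrix.taxa.index(taxon_a), matrix.taxa.index(taxon_b)
    except ValueError as exc:
        raise KeyError(str(exc)) from None
    total = 0
    for ch in matrix.characters:
        a, b = ch.states[ia], ch.states[ib]
        if a != MISSING and b != MISSING and a != b:
            total += ch.weight
    return total


def distance_frame(matrix: CharacterMatrix) -> pd.DataFrame:
    """All pairwise weighted step distances."""
    n = len(matrix.taxa)
    d = np.zeros((n, n), dtype=float)
    states = np.array([list(ch.states) for ch in matrix.characters])
    weights = np.array([ch.weight for ch in matrix.characters], dtype=float)
    for i, j in combinations(range(n), 2):
        a, b = states[:, i], states[:, j]
        mask = (a != MISSING) & (b != MISSING) & (a != b)
        d[i, j] = d[j, i] = float(weights[mask].sum())
    return pd.DataFrame(d, index=matrix.taxa, columns=matrix.taxa)


# ---------------------------------------------------------------------------
# NJ tree with character bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode, tip_set: frozenset) -> set[frozenset]:
    """Canonical non-trivial bipartitions (smaller-side frozensets)."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tip_set - side
        if 1 < len(side) < len(tip_set) - 1 or (len(side) > 1 and len(other) > 1):
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def nj_tree(matrix: CharacterMatrix, outgroup: str | None = None) -> TreeNode:
    d = distance_frame(matrix)
    dm = DistanceMatrix(d.to_numpy(), list(d.index))
    tree = nj(dm)
    if outgroup is not None and outgroup in matrix.taxa:
        tree = tree.root_at(outgroup, above=True)
    return tree


def nj_bootstrap_tree(matrix: CharacterMatrix, n_bootstrap: int = 1000,
                      seed: int | None = None,
                      outgroup: str | None = None) -> str:
    """Neighbor-joining tree with character-bootstrap support, as Newick.

    Characters are resampled with replacement, each drawn with probability
    proportional to its weight (so a weight-w character behaves like w unit
    columns); supports are the percentage of bootstrap trees containing each
    internal bipartition of the reference tree, written as internal node
    labels.  Deterministic for a fixed seed.
    """
    if len(matrix.taxa) < 4:
        raise ValueError("need at least 4 taxa for a meaningful NJ tree")
    if n_bootstrap > 0 and seed is None:
        raise ValueError("a seed is required when bootstrapping")
    ref = nj_tree(matrix, outgroup=outgroup)
    tip_set = frozenset(matrix.taxa)
    ref_parts = _bipartitions(ref, tip_set)
    support = {part: 0 for part in ref_parts}

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        states = np.array([list(ch.states) for ch in matrix.characters])
        weights = np.array([ch.weight for ch in matrix.characters], dtype=float)
        probs = weights / weights.sum()
        n_draw = int(weights.sum())
        n = len(matrix.taxa)
        # per-character pairwise difference masks (missing skipped)
        diff = np.zeros((len(matrix.characters), n, n), dtype=bool)
        for c in range(len(matrix.characters)):
            s = states[c]
            present = s != MISSING
            diff[c] = (s[:, None] != s[None, :]) & present[:, None] & present[None, :]
        for _ in range(n_bootstrap):
            draws = rng.multinomial(n_draw, probs)
            dmat = np.tensordot(draws, diff, axes=1).astype(float)
            np.fill_diagonal(dmat, 0.0)
            boot = nj(DistanceMatrix(dmat, matrix.taxa))
            parts = _bipartitions(boot, tip_set)
            for part in ref_parts & parts:
                support[part] += 1

        for node in ref.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            key = min(side, tip_set - side, key=lambda s: (len(s), sorted(s)))
            if key in support:
                node.name = str(round(100.0 * support[key] / n_bootstrap))
    return str(ref).strip()


# ---------------------------------------------------------------------------
# Median-joining network
# ---------------------------------------------------------------------------

def _vec_distance(a: tuple, b: tuple, weights: np.ndarray) -> int:
    total = 0
    for x, y, w in zip(a, b, weights):
        if x != MISSING and y != MISSING and x != y:
            total += int(w)
    return total


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _minimum_spanning_network(names: list[str], dist: dict, epsilon: int
                              ) -> list[tuple[str, str, int]]:
    """Edges of the epsilon-relaxed minimum spanning network: (u, v) is a
    link iff u and v are not connected using only links shorter than
    d(u, v) - epsilon.  At epsilon=0 this is the union of all minimum
    spanning trees (processing distance classes in ascending order against a
    union-find that lags by epsilon)."""
    by_weight: dict[int, list[tuple[str, str]]] = {}
    for u, v in combinations(names, 2):
        by_weight.setdefault(dist[u, v], []).append((u, v))
    classes = sorted(by_weight)
    uf = _UnionFind(names)
    merged = 0          # index of the next class to fold into the union-find
    edges: list[tuple[str, str, int]] = []
    for w in classes:
        while merged < len(classes) and classes[merged] < w - epsilon:
            for a, b in by_weight[classes[merged]]:
                uf.union(a, b)
            merged += 1
        for u, v in by_weight[w]:
            if uf.find(u) != uf.find(v):
                edges.append((u, v, w))
    return edges


def _median_vector(a: tuple, b: tuple, c: tuple) -> tuple:
    """Coordinate-wise majority state of three vectors; ties keep the first
    vector's state (documented tie-break)."""
    out = []
    for x, y, z in zip(a, b, c):
        if y == z:
            out.append(y)
        else:
            out.append(x)
    return tuple(out)


def median_joining_network(matrix: CharacterMatrix, epsilon: int = 0,
                           max_rounds: int = 20) -> HaploNetwork:
    """Bandelt-style median-joining network of the matrix's taxa.

    Iterates: build the epsilon-relaxed minimum spanning network, generate
    median (Steiner) vectors from connected triplets whose star connection is
    strictly shorter than their mutual links, and repeat until no new vector
    appears; median vectors that end with network degree < 3 are pruned.
    """
    if len(matrix.taxa) < 2:
        raise ValueError("need at least two taxa")
    weights = np.array([ch.weight for ch in matrix.characters], dtype=float)
    vectors: dict[str, tuple] = {
        t: tuple(ch.states[i] for ch in matrix.characters)
        for i, t in enumerate(matrix.taxa)}
    observed = set(matrix.taxa)
    mv_counter = 0

    def all_dist(vecs):
        names = list(vecs)
        return names, {(u, v): _vec_distance(vecs[u], vecs[v], weights)
                       for u, v in combinations(names, 2)} | {
                       (v, u): _vec_distance(vecs[u], vecs[v], weights)
                       for u, v in combinations(names, 2)}

    for _ in range(max_rounds):
        names, dist = all_dist(vectors)
        edges = _minimum_spanning_network(names, dist, epsilon)
        linked = {n: set() for n in names}
        for u, v, _w in edges:
            linked[u].add(v)
            linked[v].add(u)
        existing = set(vectors.values())
        new_vecs = []
        for u in names:
            for v, w in combinations(sorted(linked[u]), 2):
                m = _median_vector(vectors[u], vectors[v], vectors[w])
                if m in existing:
                    continue
                star = sum(_vec_distance(vectors[x], m, weights)
                           for x in (u, v, w))
                ring = dist[u, v] + dist[u, w] + dist[v, w]
                if star < ring:
                    existing.add(m)
                    new_vecs.append(m)
        if not new_vecs:
            break
        for m in new_vecs:
            mv_counter += 1
            vectors[f"mv{mv_counter}"] = m

    # prune median vectors of degree < 3 (they add no parsimony)
    while True:
        names, dist = all_dist(vectors)
        edges = _minimum_spanning_network(names, dist, epsilon)
        degree = {n: 0 for n in names}
        for u, v, _w in edges:
            degree[u] += 1
            degree[v] += 1
        drop = [n for n in names if n not in observed and degree[n] < 3]
        if not drop:
            break
        for n in drop:
            del vectors[n]

    nodes = {n: {"kind": "observed" if n in observed else "median",
                 "states": vectors[n]}
             for n in vectors}
    return HaploNetwork(nodes=nodes, edges=edges, connected=True)


def attach_frequencies(network: HaploNetwork, typing_df: pd.DataFrame) -> None:
    """Annotate observed nodes with colony frequency and per-region
    proportions from a typing table (columns haplotype, region)."""
    counts = typing_df.groupby("haplotype").size()
    by_region = typing_df.groupby(["haplotype", "region"]).size()
    for name, attrs in network.nodes.items():
        if attrs["kind"] != "observed":
            continue
        total = int(counts.get(name, 0))
        attrs["frequency"] = total
        if total:
            regions = by_region.loc[name]
            attrs["region_proportions"] = {
                reg: float(c) / total for reg, c in regions.items()}
        else:
            attrs["region_proportions"] = {}


def write_network(network: HaploNetwork, edge_path, node_path) -> None:
    """Plain-text export: edge list TSV and node attribute TSV."""
    with open(edge_path, "w") as fh:
        fh.write("node_a\tnode_b\tsteps\n")
        for u, v, w in sorted(network.edges):
            fh.write(f"{u}\t{v}\t{w}\n")
    with open(node_path, "w") as fh:
        fh.write("node\tkind\tfrequency\tregion_proportions\n")
        for name in sorted(network.nodes):
            attrs = network.nodes[name]
            freq = attrs.get("frequency", "")
            props = attrs.get("region_proportions", {})
            props_txt = ";".join(f"{k}={v:.4f}" for k, v in sorted(props.items()))
            fh.write(f"{name}\t{attrs['kind']}\t{freq}\t{props_txt}\n")
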