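"""Independent brute-force oracles used by the test suite.

Everything here is written against the *definition* of duplication-loss
reconciliation, not against the package's algorithms: valid mappings are
enumerated exhaustively and costed from first principles, and rootings are
enumerated on an adjacency structure built directly from the newick
string.  Deliberately slow and simple.
"""
from __future__ import annotations

import itertools
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from tfatlas.treeio import GeneTree, Node, TimeTree, split_leaf_label


def species_chain_up(s: TimeTree, node) -> List:
    """node and all its ancestors, bottom-up."""
    chain = [node]
    while chain[-1].parent is not None:
        chain.append(chain[-1].parent)
    return chain


def enumerate_valid_mappings(g: GeneTree, s: TimeTree) -> Iterator[Dict[int, Node]]:
    """All maps M: gene node -> species node with M(leaf) fixed and
    M(v) an ancestor-or-equal of LCA(M(children))."""
    internal = [v for v in g.postorder() if not v.is_leaf]
    assignment: Dict[int, Node] = {
        id(v): s.node(split_leaf_label(v.label)[0]) for v in g.postorder() if v.is_leaf
    }

    def rec(i: int) -> Iterator[Dict[int, Node]]:
        if i == len(internal):
            yield dict(assignment)
            return
        v = internal[i]
        base = assignment[id(v.children[0])]
        for c in v.children[1:]:
            base = s.lca(base, assignment[id(c)])
        for cand in species_chain_up(s, base):
            assignment[id(v)] = cand
            yield from rec(i + 1)
        del assignment[id(v)]

    return rec(0)


def mapping_cost(
    g: GeneTree, s: TimeTree, mapping: Dict[int, Node], assume_root_origin: bool
) -> Tuple[int, int]:
    """(D, L) of an arbitrary valid mapping, from the event definitions.

    v is a speciation iff M(v) = LCA(M(c1), M(c2)) and neither child maps
    to M(v) (children fall into distinct child subtrees); otherwise it is a
    duplication.  Losses on edge (v, c): depth(M(c)) - depth(M(v)) - 1 + [dup].
    """
    D = L = 0
    for v in g.postorder():
        if v.is_leaf:
            continue
        mv = mapping[id(v)]
        m1, m2 = (mapping[id(c)] for c in v.children)
        is_spec = (mv is s.lca(m1, m2)) and (m1 is not mv) and (m2 is not mv)
        if not is_spec:
            D += 1
        for mc in (m1, m2):
            L += s.depth(mc) - s.depth(mv) - (1 if is_spec else 0)
    if assume_root_origin:
        L += s.depth(mapping[id(g.root)])
    return D, L


def min_cost_over_mappings(
    g: GeneTree, s: TimeTree, assume_root_origin: bool = True
) -> Tuple[int, int, int]:
    """(min D, min L, min D+L) over all valid mappings (minimised separately)."""
    best_d = best_l = best_c = None
    for m in enumerate_valid_mappings(g, s):
        d, l = mapping_cost(g, s, m, assume_root_origin)
        best_d = d if best_d is None else min(best_d, d)
        best_l = l if best_l is None else min(best_l, l)
        best_c = d + l if best_c is None else min(best_c, d + l)
    return best_d, best_l, best_c


# -- independent rooting enumeration ---------------------------------------

def _adjacency_from_gene_tree(g: GeneTree):
    """Unrooted adjacency (label-free, object based) built by edge walking."""
    adj: Dict[int, List[Node]] = {}
    byid: Dict[int, Node] = {}

    def link(a: Node, b: Node) -> None:
        adj.setdefault(id(a), []).append(b)
        adj.setdefault(id(b), []).append(a)
        byid[id(a)] = a
        byid[id(b)] = b

    root = g.root
    if len(root.children) == 2:
        link(root.children[0], root.children[1])
        for node in g.postorder():
            if node.parent is not None and node.parent is not root:
                link(node, node.parent)
    else:
        for node in g.postorder():
            if node.parent is not None:
                link(node, node.parent)
    edges = []
    seen = set()
    for nid, nbrs in adj.items():
        for b in nbrs:
            key = frozenset((nid, id(b)))
            if key not in seen:
                seen.add(key)
                edges.append((byid[nid], b))
    return adj, edges


def all_rootings(g: GeneTree) -> List[GeneTree]:
    """Every rooted binary tree obtained by subdividing one unrooted edge."""
    adj, edges = _adjacency_from_gene_tree(g)

    def build(node: Node, come_from: Optional[Node]) -> Node:
        new = Node(label=node.label, length=0.0)
        for nbr in adj[id(node)]:
            if come_from is not None and nbr is come_from:
                continue
            new.add_child(build(nbr, node))
        return new

    out = []
    for (a, b) in edges:
        root = Node()
        root.add_child(build(a, b))
        root.add_child(build(b, a))
        out.append(GeneTree(root, rooted=True))
    return out


def min_cost_over_rootings_and_mappings(
    g: GeneTree, s: TimeTree, assume_root_origin: bool = True
) -> int:
    """Global minimum D+L over every rooting x every valid mapping."""
    best = None
    for cand in all_rootings(g):
        _, _, c = min_cost_over_mappings(cand, s, assume_root_origin)
        best = c if best is None else min(best, c)
    return best


# -- random instances -------------------------------------------------------

def random_gene_tree(
    rng: np.random.Generator,
    species: List[str],
    max_copies: int = 3,
    max_leaves: int = 8,
) -> Optional[GeneTree]:
    """Random rooted binary gene tree over a random leaf multiset."""
    labels = []
    for sp in species:
        for k in range(int(rng.integers(0, max_copies + 1))):
            labels.append(f"{sp}_{k + 1}")
    if len(labels) < 3:
        return None
    rng.shuffle(labels)
    labels = labels[:max_leaves]
    if len(labels) < 3:
        return None
    nodes = [Node(label=l, length=float(rng.uniform(0.01, 1.0))) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = Node(length=float(rng.uniform(0.01, 1.0)))
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    nodes[0].length = None
    return GeneTree(nodes[0], rooted=True)
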