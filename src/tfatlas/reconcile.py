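"""Duplication-loss parsimony reconciliation with an ILS-aware threshold.

Each orthologous-group (OG) gene tree is embedded into the dated species
tree by the LCA mapping, which attains the parsimony-minimal duplication
and loss counts for a fixed rooted gene tree.  Gene-tree/species-tree
discordance caused by incomplete lineage sorting is concentrated on short
gene-tree branches, so internal edges shorter than a threshold

    T = Ne * mu_gen        (expected substitutions per site over Ne
                            generations at per-generation rate mu_gen)

are treated as unreliable ("weak"), contracted into polytomies and
re-resolved into the binary topology of minimum duplication-loss cost.
``mu_gen`` is estimated per OG as the mean root-to-leaf path length divided
by the root age in generations (root age in years over the generation
length, default 10 years).

Conventions (all configurable):

* unit event costs ``c_d = c_l = 1``;
* stem-origin: every OG is assumed present as a single copy at the species
  root, so species subtrees hanging off the path from the species root down
  to the mapping of the gene root count one loss each;
* a loss is assigned to the species branch of the lost lineage (the
  off-path child at each skipped species node); a duplication is assigned
  to the branch terminating at its mapped species node;
* terminal gene-tree edges are never weak — a leaf's species identity is
  data, not topology.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .treeio import (
    GeneTree,
    Node,
    OrthologGroup,
    TimeTree,
    TreeError,
    split_leaf_label,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSpec",
    "Reconciliation",
    "lca_map",
    "classify_events",
    "root_gene_tree",
    "compute_mu",
    "weak_edges",
    "contract_weak_edges",
    "rearrange_weak",
    "reconcile_og",
    "PolytomyTooLarge",
]

DEFAULT_GENERATION_YEARS = 10.0
NE_SWEEP = (1e4, 1e5, 1e6, 1e7)


class PolytomyTooLarge(TreeError):
    """A weak-edge polytomy exceeded the hard resolution cap."""


@dataclass(frozen=True)
class ThresholdSpec:
    """Weak-branch threshold T = Ne * mu_gen (substitutions/site).

    ``mu_gen`` is per generation; if not supplied it is estimated per OG
    from the gene tree and the species-root age via :func:`compute_mu`.
    """

    ne: float = 1e6
    generation_years: float = DEFAULT_GENERATION_YEARS
    mu_gen: Optional[float] = None

    def __post_init__(self):
        if self.ne < 0:
            raise ValueError("Ne must be >= 0")
        if self.mu_gen is not None and self.mu_gen < 0:
            raise ValueError("mu_gen must be >= 0")

    def threshold(self, mu_gen: Optional[float] = None) -> float:
        mu = self.mu_gen if mu_gen is None else mu_gen
        if mu is None:
            raise ValueError("mu_gen not set; estimate it with compute_mu first")
        return self.ne * mu


@dataclass
class Reconciliation:
    """Result of embedding one gene tree into the species tree.

    ``duplications`` and ``losses`` hold species-branch labels (the branch
    is named by its child node); duplications additionally record the gene
    node.  ``mapping`` maps gene :class:`Node` objects to species nodes.
    """

    og_id: str
    mapping: Dict[int, Node]
    duplications: List[Tuple[str, str]]  # (gene node repr, species branch)
    losses: List[str]  # species branch labels
    cost_dup: float = 1.0
    cost_loss: float = 1.0
    resolved_tree: Optional[GeneTree] = None
    approximate: bool = False

    @property
    def n_duplications(self) -> int:
        return len(self.duplications)

    @property
    def n_losses(self) -> int:
        return len(self.losses)

    @property
    def cost(self) -> float:
        return self.cost_dup * self.n_duplications + self.cost_loss * self.n_losses

    def events_by_branch(self) -> Dict[str, Dict[str, int]]:
        out: Dict[str, Dict[str, int]] = {}
        for _, br in self.duplications:
            out.setdefault(br, {"gain": 0, "loss": 0})["gain"] += 1
        for br in self.losses:
            out.setdefault(br, {"gain": 0, "loss": 0})["loss"] += 1
        return out

    def event_rows(self) -> List[Tuple[str, str, str]]:
        rows = [(self.og_id, "gain", br) for _, br in self.duplications]
        rows += [(self.og_id, "loss", br) for br in self.losses]
        return rows


# ---------------------------------------------------------------------------
# LCA mapping and event classification
# ---------------------------------------------------------------------------

def _leaf_species_node(leaf: Node, s: TimeTree) -> Node:
    species, _ = split_leaf_label(leaf.label)
    if species not in s:
        raise TreeError(
            f"leaf {leaf.label!r}: species {species!r} not in species tree"
        )
    return s.node(species)


def lca_map(
    g: GeneTree, s: TimeTree, leaf_mapping: Optional[Dict[int, Node]] = None
) -> Dict[int, Node]:
    """LCA mapping: gene node -> species node, one postorder pass.

    Keys are ``id(gene_node)``.  ``leaf_mapping`` overrides the default
    leaf-label lookup (used internally for polytomy sub-problems whose
    pseudo-leaves map to internal species nodes).
    """
    mapping: Dict[int, Node] = {}
    for node in g.postorder():
        if node.is_leaf:
            if leaf_mapping is not None:
                mapping[id(node)] = leaf_mapping[id(node)]
            else:
                mapping[id(node)] = _leaf_species_node(node, s)
        else:
            it = iter(node.children)
            m = mapping[id(next(it))]
            for child in it:
                m = s.lca(m, mapping[id(child)])
            mapping[id(node)] = m
    return mapping


def _path_losses(s: TimeTree, top: Node, bottom: Node, include_top: bool) -> List[str]:
    """Species branches losing the lineage on the path top -> bottom.

    At every species node the lineage passes through without branching into
    both children, the off-path child is lost.  ``include_top`` is True for
    duplication parents (the lineage must also descend through ``top``).
    """
    losses: List[str] = []
    node = bottom
    while node is not top:
        parent = node.parent
        if parent is top and not include_top:
            break
        losses.append(s.sibling(node).label)
        node = parent
    return losses


def classify_events(
    g: GeneTree,
    s: TimeTree,
    mapping: Optional[Dict[int, Node]] = None,
    assume_root_origin: bool = True,
    cost_dup: float = 1.0,
    cost_loss: float = 1.0,
    og_id: str = "",
) -> Reconciliation:
    """Classify duplications and losses implied by an LCA mapping.

    A gene node ``v`` is a duplication iff one of its children maps to the
    same species node as ``v``; losses on the gene edge ``(v, c)`` number
    ``depth(M(c)) - depth(M(v)) - [v is a speciation]`` and are assigned to
    the off-path child branch at each skipped species node.  With
    ``assume_root_origin`` the OG is taken to exist at the species root, so
    the branches hanging off the path from the species root down to
    ``M(root)`` each add one stem loss.
    """
    if mapping is None:
        mapping = lca_map(g, s)
    duplications: List[Tuple[str, str]] = []
    losses: List[str] = []
    for v in g.postorder():
        if v.is_leaf:
            continue
        mv = mapping[id(v)]
        is_dup = any(mapping[id(c)] is mv for c in v.children)
        if is_dup:
            duplications.append((f"g{v.index}", mv.label))
        for c in v.children:
            losses.extend(_path_losses(s, mv, mapping[id(c)], include_top=is_dup))
    if assume_root_origin:
        node = mapping[id(g.root)]
        while node.parent is not None:
            losses.append(s.sibling(node).label)
            node = node.parent
    return Reconciliation(
        og_id=og_id,
        mapping=mapping,
        duplications=duplications,
        losses=losses,
        cost_dup=cost_dup,
        cost_loss=cost_loss,
    )


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def _unrooted_edges(g: GeneTree):
    """Adjacency representation of the unrooted version of ``g``.

    A rooted binary tree is unrooted by suppressing its root node (joining
    the two root edges).  Returns (adjacency dict node-id -> list of
    (neighbour, length), node lookup, edge list).
    """
    adj: Dict[int, List[Tuple[Node, float]]] = {}
    byid: Dict[int, Node] = {}

    def add(a: Node, b: Node, length: float) -> None:
        adj.setdefault(id(a), []).append((b, length))
        adj.setdefault(id(b), []).append((a, length))
        byid[id(a)] = a
        byid[id(b)] = b

    root = g.root
    skip = set()
    if len(root.children) == 2:
        c1, c2 = root.children
        add(c1, c2, (c1.length or 0.0) + (c2.length or 0.0))
        skip = {id(root)}
    for node in g.postorder():
        if node.parent is None or id(node.parent) in skip:
            continue
        add(node, node.parent, node.length or 0.0)
    edges = []
    seen = set()
    for nid, nbrs in adj.items():
        for (b, length) in nbrs:
            key = frozenset((nid, id(b)))
            if key not in seen:
                seen.add(key)
                edges.append((byid[nid], b, length))
    return adj, edges


def _root_on_edge(adj, a: Node, b: Node, length: float) -> Node:
    """Build a fresh rooted tree with the root placed on edge (a, b)."""

    def build(node: Node, come_from: Node, stem: float) -> Node:
        new = Node(label=node.label, length=stem)
        for (nbr, ln) in adj[id(node)]:
            if nbr is come_from:
                continue
            new.add_child(build(nbr, node, ln))
        return new

    root = Node()
    root.add_child(build(a, b, length / 2.0))
    root.add_child(build(b, a, length / 2.0))
    return root


def root_gene_tree(
    g: GeneTree,
    s: TimeTree,
    assume_root_origin: bool = True,
    cost_dup: float = 1.0,
    cost_loss: float = 1.0,
) -> GeneTree:
    """Root an (un)rooted gene tree at the edge of minimum DL cost.

    All edge rootings are scored by LCA reconciliation cost.  Ties are
    broken by (1) the rooting whose root maps closest to the species root,
    then (2) the lexicographically smallest canonical newick, so the result
    is deterministic.
    """
    if g.n_leaves < 3:
        out = GeneTree.from_newick(g.to_newick())
        out.rooted = True
        return out
    adj, edges = _unrooted_edges(g)
    best = None
    for (a, b, length) in edges:
        cand = GeneTree(_root_on_edge(adj, a, b, length), rooted=True)
        rec = classify_events(
            cand, s,
            assume_root_origin=assume_root_origin,
            cost_dup=cost_dup, cost_loss=cost_loss,
        )
        root_depth = s.depth(rec.mapping[id(cand.root)])
        key = (rec.cost, root_depth, cand.to_newick())
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1]


# ---------------------------------------------------------------------------
# threshold machinery
# ---------------------------------------------------------------------------

def compute_mu(
    og: OrthologGroup | GeneTree,
    root_age_years: float,
    generation_years: float = DEFAULT_GENERATION_YEARS,
) -> float:
    """Per-generation substitution rate of an OG.

    mu_gen = generation_years * (mean root-to-leaf path length in
    substitutions/site) / (root age in years).
    """
    if root_age_years <= 0:
        raise ValueError("root age must be positive")
    tree = og.tree if isinstance(og, OrthologGroup) else og
    depth: Dict[int, float] = {id(tree.root): 0.0}
    total, nleaf = 0.0, 0
    for node in tree.root.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
        if node.is_leaf:
            total += depth[id(node)]
            nleaf += 1
    mean_path = total / nleaf
    if mean_path == 0.0:
        logger.warning("zero-length gene tree: mu_gen = 0")
    return generation_years * mean_path / root_age_years


def weak_edges(g: GeneTree, threshold: float) -> List[Node]:
    """Internal gene-tree edges with length < threshold.

    An edge is identified by its child node; terminal edges are never weak
    (a leaf's species identity is observed data, not topology).
    """
    out = []
    for node in g.postorder():
        if node.parent is None or node.is_leaf:
            continue
        if (node.length or 0.0) < threshold:
            out.append(node)
    return out


def contract_weak_edges(g: GeneTree, threshold: float) -> GeneTree:
    """Collapse weak internal edges into polytomies (new tree)."""
    out = GeneTree.from_newick(g.to_newick(), rooted=g.rooted)
    weak_ids = {id(n) for n in weak_edges(out, threshold)}
    changed = True
    while changed:
        changed = False
        for node in list(out.root.preorder()):
            if id(node) in weak_ids and node.parent is not None:
                parent = node.parent
                i = parent.children.index(node)
                parent.children[i:i + 1] = node.children
                for c in node.children:
                    c.parent = parent
                weak_ids.discard(id(node))
                changed = True
    out._reindex()
    return out


# -- polytomy resolution ----------------------------------------------------

def _enumerate_topologies(k: int):
    """All rooted binary topologies over items 0..k-1, as nested tuples.

    Deterministic sequential-insertion order; (2k-3)!! trees.
    """
    trees = [0]
    for item in range(1, k):
        new_trees = []
        for t in trees:
            for edited in _insert_everywhere(t, item):
                new_trees.append(edited)
        trees = new_trees
    return trees


def _insert_everywhere(t, item):
    # attach `item` above the subtree t itself
    yield (t, item)
    if isinstance(t, tuple):
        a, b = t
        for ea in _insert_everywhere(a, item):
            yield (ea, b)
        for eb in _insert_everywhere(b, item):
            yield (a, eb)


def _build_from_shape(shape, subtrees: Sequence[Node]) -> Node:
    if isinstance(shape, int):
        return subtrees[shape]
    left = _build_from_shape(shape[0], subtrees)
    right = _build_from_shape(shape[1], subtrees)
    node = Node(length=0.0)
    node.add_child(left)
    node.add_child(right)
    return node


def _local_cost(
    shape, maps: Sequence[Node], s: TimeTree, cost_dup: float, cost_loss: float
) -> float:
    """DL cost of one polytomy resolution, evaluated locally.

    The mapping of the polytomy root is invariant under resolution (it is
    the LCA of all its leaves), so resolutions can be scored independently
    of the rest of the tree: duplications/losses internal to the resolved
    subtree plus the root's own duplication status.
    """

    def rec(sh):
        # returns (species node, cost)
        if isinstance(sh, int):
            return maps[sh], 0.0
        (ma, ca), (mb, cb) = rec(sh[0]), rec(sh[1])
        mv = s.lca(ma, mb)
        is_dup = mv is ma or mv is mb
        cost = ca + cb + (cost_dup if is_dup else 0.0)
        for mc in (ma, mb):
            n_loss = s.depth(mc) - s.depth(mv) - (0 if is_dup else 1)
            cost += cost_loss * max(0, n_loss)
        return mv, cost

    return rec(shape)[1]


def _resolve_polytomy(
    node: Node,
    maps: List[Node],
    s: TimeTree,
    cost_dup: float,
    cost_loss: float,
    k_max: int,
    hard_cap: int,
) -> Tuple[List[Node], bool]:
    """Return new children structure for a polytomy node (as a 2-list),
    choosing the binary resolution of minimum local DL cost.

    Exhaustive for <= k_max children; greedy pairwise agglomeration above
    (flagged approximate); beyond ``hard_cap`` raises
    :class:`PolytomyTooLarge`.
    """
    subtrees = list(node.children)
    k = len(subtrees)
    if k > hard_cap:
        raise PolytomyTooLarge(
            f"polytomy with {k} children exceeds the hard cap {hard_cap}"
        )
    if k <= k_max:
        best_shape, best_cost = None, math.inf
        for shape in _enumerate_topologies(k):
            cost = _local_cost(shape, maps, s, cost_dup, cost_loss)
            if cost < best_cost:
                best_shape, best_cost = shape, cost
        new_root = _build_from_shape(best_shape, subtrees)
        return list(new_root.children) if len(subtrees) > 1 else subtrees, False
    # greedy agglomeration: repeatedly join the cheapest pair
    items: List[Tuple[Node, Node]] = list(zip(subtrees, maps))  # (subtree, map)
    while len(items) > 2:
        best = None
        for i, j in itertools.combinations(range(len(items)), 2):
            mi, mj = items[i][1], items[j][1]
            mv = s.lca(mi, mj)
            is_dup = mv is mi or mv is mj
            cost = cost_dup if is_dup else 0.0
            for mc in (mi, mj):
                cost += cost_loss * max(
                    0, s.depth(mc) - s.depth(mv) - (0 if is_dup else 1)
                )
            if best is None or cost < best[0]:
                best = (cost, i, j, mv)
        _, i, j, mv = best
        joined = Node(length=0.0)
        joined.add_child(items[i][0])
        joined.add_child(items[j][0])
        items = [it for idx, it in enumerate(items) if idx not in (i, j)]
        items.append((joined, mv))
    return [items[0][0], items[1][0]], True


def rearrange_weak(
    g: GeneTree,
    s: TimeTree,
    threshold: float,
    assume_root_origin: bool = True,
    cost_dup: float = 1.0,
    cost_loss: float = 1.0,
    k_max: int = 6,
    hard_cap: int = 12,
    og_id: str = "",
) -> Reconciliation:
    """Contract weak edges, re-resolve polytomies at minimum DL cost,
    and reconcile the resolved tree.

    The original binary topology is among the candidate resolutions of each
    polytomy, and the original reconciliation is kept whenever resolution
    does not improve the cost, so ``cost(resolved) <= cost(original)``.
    """
    baseline = classify_events(
        g, s, assume_root_origin=assume_root_origin,
        cost_dup=cost_dup, cost_loss=cost_loss, og_id=og_id,
    )
    if threshold <= 0:
        baseline.resolved_tree = g
        return baseline
    collapsed = contract_weak_edges(g, threshold)
    approximate = False
    mapping = lca_map(collapsed, s)
    for node in list(collapsed.postorder()):
        if len(node.children) > 2:
            maps = [mapping[id(c)] for c in node.children]
            new_children, approx = _resolve_polytomy(
                node, maps, s, cost_dup, cost_loss, k_max, hard_cap
            )
            approximate = approximate or approx
            node.children = []
            for c in new_children:
                node.add_child(c)
            # refresh mapping for the newly created internal nodes
            for sub in node.postorder():
                if id(sub) not in mapping:
                    mapping[id(sub)] = s.lca(
                        mapping[id(sub.children[0])], mapping[id(sub.children[1])]
                    )
    collapsed._reindex()
    resolved = GeneTree(collapsed.root, rooted=True)
    rec = classify_events(
        resolved, s, assume_root_origin=assume_root_origin,
        cost_dup=cost_dup, cost_loss=cost_loss, og_id=og_id,
    )
    rec.approximate = approximate
    rec.resolved_tree = resolved
    if rec.cost > baseline.cost:
        baseline.resolved_tree = g
        return baseline
    return rec


def reconcile_og(
    og: OrthologGroup,
    s: TimeTree,
    threshold_spec: Optional[ThresholdSpec] = None,
    assume_root_origin: bool = True,
    cost_dup: float = 1.0,
    cost_loss: float = 1.0,
    k_max: int = 6,
    hard_cap: int = 12,
) -> Reconciliation:
    """Full per-OG step: root (if needed) -> threshold -> rearrange -> classify."""
    og.tree.check_species(s)
    g = og.tree
    if not g.rooted:
        g = root_gene_tree(
            g, s, assume_root_origin=assume_root_origin,
            cost_dup=cost_dup, cost_loss=cost_loss,
        )
    if threshold_spec is None:
        threshold = 0.0
    else:
        mu = threshold_spec.mu_gen
        if mu is None:
            mu = compute_mu(
                g, root_age_years=s.root_age * 1e6,
                generation_years=threshold_spec.generation_years,
            )
        threshold = threshold_spec.threshold(mu)
    return rearrange_weak(
        g, s, threshold,
        assume_root_origin=assume_root_origin,
        cost_dup=cost_dup, cost_loss=cost_loss,
        k_max=k_max, hard_cap=hard_cap, og_id=og.og_id,
    )
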