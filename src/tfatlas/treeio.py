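"""Trees and tables shared by every stage of the pipeline.

Two tree flavours are distinguished throughout:

* :class:`TimeTree` — a rooted, binary, time-calibrated species tree.  Every
  node carries an age in million years (Mya); leaves sit at age 0 unless
  stated otherwise, and the branch above a node spans
  ``[age(node), age(parent)]``.  Branch *durations* (My) drive all per-My
  rates downstream.
* :class:`GeneTree` — a gene-family tree whose branch lengths are expected
  substitutions per site and whose leaves are named
  ``<species_id>_<copy_index>`` (``_`` is the reserved separator; the copy
  index is everything after the last underscore).

Newick parsing goes through :mod:`dendropy`; serialisation is a small
canonical writer (children ordered by smallest descendant leaf label) so
that parse -> write round trips are byte-stable.
"""
from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TreeError",
    "Node",
    "TimeTree",
    "GeneTree",
    "OrthologGroup",
    "parse_newick",
    "read_table",
    "split_leaf_label",
]

SPECIES_SEPARATOR = "_"


class TreeError(ValueError):
    """Malformed tree input or violated tree invariant."""


class Node:
    """A node of a rooted tree (shared by species and gene trees)."""

    __slots__ = ("label", "children", "parent", "length", "age", "index")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None
        self.length = length  # length of the branch above this node
        self.age: Optional[float] = None  # Mya; set on TimeTree nodes
        self.index: int = -1  # postorder index, set at tree construction

    # -- structure -------------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> List["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label!r}>"


def split_leaf_label(label: str) -> Tuple[str, str]:
    """Split a gene-tree leaf label into (species_id, copy_index).

    The part after the *last* underscore is the copy index, so species ids
    may themselves contain underscores.
    """
    if SPECIES_SEPARATOR not in label:
        raise TreeError(
            f"gene-tree leaf {label!r} lacks the '<species>_<copy>' separator"
        )
    species, _, copy = label.rpartition(SPECIES_SEPARATOR)
    return species, copy


def _min_leaf_key(node: Node, cache: Dict[int, str]) -> str:
    key = cache.get(id(node))
    if key is None:
        if node.is_leaf:
            key = node.label or ""
        else:
            key = min(_min_leaf_key(c, cache) for c in node.children)
        cache[id(node)] = key
    return key


def _canonical_sort(root: Node) -> None:
    cache: Dict[int, str] = {}
    for node in root.postorder():
        if node.children:
            node.children.sort(key=lambda c: _min_leaf_key(c, cache))


def _format_length(x: Optional[float]) -> str:
    if x is None:
        return ""
    return f":{x:.12g}"


def _write_newick(root: Node, include_internal_labels: bool = False) -> str:
    parts: List[str] = []

    def rec(node: Node) -> None:
        if node.is_leaf:
            parts.append(node.label or "")
        else:
            parts.append("(")
            for i, child in enumerate(node.children):
                if i:
                    parts.append(",")
                rec(child)
            parts.append(")")
            if include_internal_labels and node.label:
                parts.append(node.label)
        if node.parent is not None:
            parts.append(_format_length(node.length))

    rec(root)
    parts.append(";")
    return "".join(parts)


def _from_dendropy(dtree: dendropy.Tree) -> Node:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return convert(dtree.seed_node)


def _parse_newick_to_node(text: str) -> Node:
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from exc
    return _from_dendropy(dtree)


class _BaseTree:
    """Indexing, traversal and canonical serialisation shared by both trees."""

    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    def _reindex(self) -> None:
        self._postorder = list(self.root.postorder())
        for i, node in enumerate(self._postorder):
            node.index = i
        self._leaves = [n for n in self._postorder if n.is_leaf]

    def postorder(self) -> List[Node]:
        return self._postorder

    @property
    def leaves(self) -> List[Node]:
        return self._leaves

    @property
    def leaf_labels(self) -> List[str]:
        return [n.label for n in self._leaves]

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def copy(self):
        return type(self).from_newick(self.to_newick())


class TimeTree(_BaseTree):
    """Rooted binary species tree with node ages in Mya.

    Construct either from an ultrametric newick (branch lengths read as My,
    leaf ages 0) via :func:`parse_newick`, or programmatically from a root
    :class:`Node` whose ``age`` attributes are already set.
    """

    AGE_TOL = 1e-6

    def __init__(self, root: Node):
        super().__init__(root)
        # ages quantized to 1e-6 My (~1 year): far below any biological
        # signal, far above float noise, so serialisation is byte-stable
        for node in self._postorder:
            if node.age is not None:
                node.age = round(node.age, 6)
        self._label_internal_nodes()
        self._validate()
        self._node_by_label = {n.label: n for n in self._postorder}
        self._depth = {}
        for node in self.root.preorder():
            self._depth[id(node)] = (
                0 if node.parent is None else self._depth[id(node.parent)] + 1
            )
        self._build_lca_table()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "TimeTree":
        root = _parse_newick_to_node(text)
        # ages from ultrametric branch lengths: depth from root, then invert
        dist = {id(root): 0.0}
        maxdist = 0.0
        for node in root.preorder():
            if node.parent is not None:
                if node.length is None:
                    raise TreeError(
                        f"species-tree branch above {node.label!r} has no length"
                    )
                dist[id(node)] = dist[id(node.parent)] + node.length
                maxdist = max(maxdist, dist[id(node)])
        for node in root.preorder():
            node.age = maxdist - dist[id(node)]
            if node.is_leaf and abs(node.age) > cls.AGE_TOL * max(1.0, maxdist):
                raise TreeError(
                    f"species tree is not ultrametric: leaf {node.label!r} sits "
                    f"at age {node.age:.6g}, expected 0"
                )
            if node.is_leaf:
                node.age = 0.0
        return cls(root)

    def _label_internal_nodes(self) -> None:
        """Assign deterministic labels N0, N1, ... to unlabeled internal nodes.

        Numbering follows a canonical preorder (children ordered by smallest
        descendant leaf), so the same topology always gets the same labels.
        """
        _canonical_sort(self.root)
        self._reindex()
        taken = {n.label for n in self._postorder if n.label}
        counter = 0
        for node in self.root.preorder():
            if not node.is_leaf and not node.label:
                while f"N{counter}" in taken:
                    counter += 1
                node.label = f"N{counter}"
                counter += 1

    def _validate(self) -> None:
        labels = [n.label for n in self._leaves]
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels in species tree")
        for node in self._postorder:
            if node.children and len(node.children) != 2:
                raise TreeError(
                    f"species tree must be binary; node {node.label!r} has "
                    f"{len(node.children)} children"
                )
            if node.age is None:
                raise TreeError(f"node {node.label!r} has no age")
            if node.parent is not None:
                dur = node.parent.age - node.age
                if dur <= 0:
                    raise TreeError(
                        f"non-positive branch duration above {node.label!r}: "
                        f"parent age {node.parent.age:.6g}, child age {node.age:.6g}"
                    )

    # -- queries ---------------------------------------------------------
    @property
    def root_age(self) -> float:
        return float(self.root.age)

    def node(self, label: str) -> Node:
        try:
            return self._node_by_label[label]
        except KeyError:
            raise TreeError(f"no species-tree node labelled {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._node_by_label

    def depth(self, node: Node) -> int:
        return self._depth[id(node)]

    def _build_lca_table(self) -> None:
        n = len(self._postorder)
        table = np.empty((n, n), dtype=np.int32)
        # ancestry via postorder intervals: descendants of v form a
        # contiguous postorder block ending at v
        start = np.empty(n, dtype=np.int32)
        for node in self._postorder:
            start[node.index] = (
                node.index if node.is_leaf else start[node.children[0].index]
            )
        self._sub_start = start
        for a in self._postorder:
            for b in self._postorder:
                x = a
                while not (start[x.index] <= b.index <= x.index):
                    x = x.parent
                table[a.index, b.index] = x.index
        self._lca_table = table

    def lca(self, a: Node, b: Node) -> Node:
        return self._postorder[self._lca_table[a.index, b.index]]

    def is_ancestor_or_equal(self, anc: Node, node: Node) -> bool:
        return self._sub_start[anc.index] <= node.index <= anc.index

    def sibling(self, node: Node) -> Node:
        c1, c2 = node.parent.children
        return c2 if c1 is node else c1

    def branch_durations(self) -> Dict[str, float]:
        """Map branch (labelled by its child node) -> duration in My."""
        out = {}
        for node in self._postorder:
            if node.parent is not None:
                dur = node.parent.age - node.age
                if dur <= 0:
                    raise TreeError(f"non-positive duration above {node.label!r}")
                out[node.label] = dur
        return out

    def to_newick(self) -> str:
        # durations rounded to 1e-9 My: far above accumulated float error,
        # so parse -> write is byte-idempotent
        _canonical_sort(self.root)
        for node in self.root.preorder():
            node.length = (
                None if node.parent is None
                else round(node.parent.age - node.age, 6)
            )
        return _write_newick(self.root, include_internal_labels=True)


class GeneTree(_BaseTree):
    """Gene-family tree; branch lengths in substitutions/site.

    Leaves are ``<species_id>_<copy_index>``.  ``rooted`` records whether the
    root placement is meaningful; unrooted trees must pass through
    :func:`tfatlas.reconcile.root_gene_tree` before reconciliation.
    """

    def __init__(self, root: Node, rooted: bool = True):
        super().__init__(root)
        self.rooted = rooted
        labels = self.leaf_labels
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels in gene tree")
        for label in labels:
            split_leaf_label(label)
        for node in self._postorder:
            if node.parent is not None and node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length above {node.label!r}")

    @classmethod
    def from_newick(cls, text: str, rooted: bool = True) -> "GeneTree":
        root = _parse_newick_to_node(text)
        # a trifurcating root is the usual unrooted-ML convention
        if len(root.children) > 2:
            rooted = False
        return cls(root, rooted=rooted)

    @property
    def species(self) -> List[str]:
        return sorted({split_leaf_label(l)[0] for l in self.leaf_labels})

    def copy_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for label in self.leaf_labels:
            sp, _ = split_leaf_label(label)
            counts[sp] = counts.get(sp, 0) + 1
        return counts

    def check_species(self, s: TimeTree) -> None:
        missing = [sp for sp in self.species if sp not in s]
        if missing:
            raise TreeError(
                f"gene-tree species absent from species tree: {missing}"
            )

    def total_length(self) -> float:
        return sum(
            n.length or 0.0 for n in self._postorder if n.parent is not None
        )

    def to_newick(self) -> str:
        _canonical_sort(self.root)
        return _write_newick(self.root)


@dataclass
class OrthologGroup:
    """A gene family with a single origin at the species root."""

    og_id: str
    tree: GeneTree
    member_counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.member_counts:
            self.member_counts = self.tree.copy_counts()
        if self.n_members == 0:
            raise TreeError(f"orthologous group {self.og_id} is empty")

    @property
    def n_members(self) -> int:
        return sum(self.member_counts.values())

    def passes_size_filter(self, min_members: int = 4) -> bool:
        """The analysis keeps only groups with more than three members."""
        return self.n_members >= min_members


def parse_newick(text: str, kind: str = "gene"):
    """Parse a newick string into a :class:`TimeTree` or :class:`GeneTree`.

    ``kind='species'`` reads branch lengths as My and requires an
    ultrametric, binary tree; ``kind='gene'`` reads lengths as
    substitutions/site.
    """
    if kind == "species":
        return TimeTree.from_newick(text)
    if kind == "gene":
        return GeneTree.from_newick(text)
    raise ValueError(f"kind must be 'species' or 'gene', got {kind!r}")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

_SCHEMAS = ("presence", "trait", "interaction")


def read_table(path_or_buf, schema: str, species_tree: Optional[TimeTree] = None):
    """Read a TSV table of one of the pipeline's three schemas.

    presence
        rows = species, columns = OG ids, cells strictly 0/1.
    trait
        rows = species, columns = traits, cells 0/1 or empty (missing).
    interaction
        two columns ``tf_og_id`` and ``tg_id``.

    If a ``species_tree`` is given, rows whose species is not in the tree are
    dropped with a logged warning (presence/trait schemas only).
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"schema must be one of {_SCHEMAS}, got {schema!r}")
    if schema == "interaction":
        df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
        for col in ("tf_og_id", "tg_id"):
            if col not in df.columns:
                raise ValueError(f"interaction table lacks required column {col!r}")
        return df[["tf_og_id", "tg_id"]]

    df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    allow_missing = schema == "trait"
    for col in df.columns:
        vals = df[col]
        bad = ~(vals.isin([0, 1]) | (vals.isna() if allow_missing else False))
        if bad.any():
            row = df.index[np.where(bad)[0][0]]
            raise ValueError(
                f"non-binary cell in {schema} table at row {row!r}, "
                f"column {col!r}: {vals.loc[row]!r}"
            )
    if species_tree is not None:
        unknown = [sp for sp in df.index if sp not in species_tree]
        if unknown:
            logger.warning(
                "%d species in %s table absent from species tree, dropped: %s",
                len(unknown), schema, ", ".join(map(str, unknown[:10])),
            )
            df = df.drop(index=unknown)
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
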