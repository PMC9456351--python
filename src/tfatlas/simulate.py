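"""Synthetic gene families, traits and target-gene rates with ground truth.

The generator mirrors the statistical structure the analysis assumes:

* a dated species tree (pure-birth expansion topology, non-root split ages
  drawn as uniform order statistics on ``[0, A]`` with the root pinned at
  the given age ``A``);
* gene families born as a single copy at the species root, evolving down
  the species tree under a branch-wise linear birth-death process
  (duplication rate ``lambda(b)`` and loss rate ``mu_loss(b)`` per gene
  lineage per My);
* branch lengths in substitutions/site obtained from the time spans via a
  relaxed clock ``l = r * t * eps`` with lognormal branch noise;
* incomplete-lineage-sorting-like discordance emulated phenomenologically:
  short internal edges are hit by a random nearest-neighbour interchange
  and get their length resampled — matching how the downstream threshold
  treats ILS, as short-branch topological noise;
* binary traits drawn from a logistic model on the presence/absence of a
  small causal set of families;
* target-gene terminal rates reduced by a factor ``1 - delta`` in species
  lacking the regulating factor.

Every stochastic output carries a :class:`SimulationTruth` record: the full
event list, per-branch totals, and the *observable projection* — the events
a parsimony reconciliation of the pruned (surviving) tree can in principle
recover: duplications located at the most recent common ancestor of both
daughters' surviving species, and one loss per maximal extinct subtree
hanging off a surviving lineage.  The projection is computed here, on the
simulator's own lineage records, independent of the reconcile module.
"""
from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .treeio import GeneTree, Node, OrthologGroup, TimeTree

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "TrueEvent",
    "simulate_species_timetree",
    "simulate_gene_family",
    "assign_branch_lengths",
    "perturb_ils",
    "simulate_og_batch",
    "simulate_presence_matrix",
    "simulate_traits",
    "simulate_tg_rates",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Rates are per gene lineage per My; ``subst_rate`` is substitutions per
    site per My (0.002/My ~ 2e-9/site/year, a typical mammalian average).
    ``ils_length`` is matched to the expected weak-branch threshold at
    Ne = 10^6 for the default clock (mu_gen ~ 2e-8 per generation at a
    10-year generation gives T = 0.02 substitutions/site).
    """

    n_taxa: int = 16
    root_age: float = 170.0  # Mya
    n_ogs: int = 200
    dup_rate: float = 0.002
    loss_rate: float = 0.003
    dup_rate_overrides: Dict[str, float] = field(default_factory=dict)
    loss_rate_overrides: Dict[str, float] = field(default_factory=dict)
    subst_rate: float = 0.002  # subs/site/My
    sigma_r: float = 0.3  # lognormal branch-rate noise
    p_ils: float = 0.2
    ils_length: float = 0.02  # subs/site; short-branch scale of the ILS noise
    # trait model
    n_causal: int = 5
    trait_beta: float = 2.0
    trait_beta0: float = 0.0
    # target-gene model
    tg_base_rate: float = 0.002  # subs/site/My
    tg_delta: float = 0.3
    tg_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        for name in ("dup_rate", "loss_rate", "subst_rate", "tg_base_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_ils <= 1.0:
            raise ValueError("p_ils must be in [0, 1]")
        if not 0.0 <= self.tg_delta < 1.0:
            raise ValueError("tg_delta must be in [0, 1)")

    def dup_rate_on(self, branch: str) -> float:
        return self.dup_rate_overrides.get(branch, self.dup_rate)

    def loss_rate_on(self, branch: str) -> float:
        return self.loss_rate_overrides.get(branch, self.loss_rate)


@dataclass(frozen=True)
class TrueEvent:
    kind: str  # "gain" | "loss"
    branch: str  # species branch label (child node of the branch)
    age: float  # Mya

    def __post_init__(self):
        if self.kind not in ("gain", "loss"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class SimulationTruth:
    """Ground truth for one simulated gene family."""

    og_id: str
    events: List[TrueEvent] = field(default_factory=list)
    obs_gains: Counter = field(default_factory=Counter)
    obs_losses: Counter = field(default_factory=Counter)
    extinct: bool = False

    def per_branch_totals(self) -> Dict[str, Dict[str, int]]:
        out: Dict[str, Dict[str, int]] = {}
        for ev in self.events:
            out.setdefault(ev.branch, {"gain": 0, "loss": 0})[ev.kind] += 1
        return out

    @property
    def n_gains(self) -> int:
        return sum(1 for ev in self.events if ev.kind == "gain")

    @property
    def n_losses(self) -> int:
        return sum(1 for ev in self.events if ev.kind == "loss")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_timetree(n_taxa: int, root_age: float, seed) -> TimeTree:
    """Random dated species tree: rooted, binary, ultrametric, root at A.

    Topology grows by a pure-birth expansion (each dangling lineage equally
    likely to split next); the n-2 non-root split ages are uniform order
    statistics on [0, A], the root is pinned at A.  Leaves are labelled
    S1..Sn in creation order.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if root_age <= 0:
        raise ValueError("root age must be positive")
    rng = _rng(seed)
    inner_ages = np.sort(rng.uniform(0.0, root_age, size=n_taxa - 2))[::-1]
    root = Node()
    root.age = float(root_age)
    open_slots: List[Node] = [root, root]
    for age in inner_ages:
        i = int(rng.integers(len(open_slots)))
        parent = open_slots.pop(i)
        v = Node()
        v.age = float(age)
        parent.add_child(v)
        open_slots.extend([v, v])
    for j, parent in enumerate(open_slots, start=1):
        leaf = Node(label=f"S{j}")
        leaf.age = 0.0
        parent.add_child(leaf)
    return TimeTree(root)


# ---------------------------------------------------------------------------
# gene-family birth-death along the species tree
# ---------------------------------------------------------------------------

class _LinNode:
    """Node of the complete (extinct lineages included) gene history."""

    __slots__ = ("kind", "species", "age", "children")

    def __init__(self, kind: str, species: Node, age: float):
        self.kind = kind  # "spec" | "dup" | "loss" | "leaf"
        self.species = species  # bottom node of the branch the event sits on
        self.age = age
        self.children: List["_LinNode"] = []


def _evolve_branch(
    sp: Node, age_top: float, cfg: SimulationConfig, rng: np.random.Generator
) -> _LinNode:
    """One gene lineage entering the branch above ``sp`` at ``age_top``."""
    lam = cfg.dup_rate_on(sp.label)
    mu = cfg.loss_rate_on(sp.label)
    total = lam + mu
    age = age_top
    while True:
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        t = age - wait
        if t <= sp.age:
            break
        if rng.random() < lam / total:
            node = _LinNode("dup", sp, t)
            node.children = [
                _evolve_branch(sp, t, cfg, rng),
                _evolve_branch(sp, t, cfg, rng),
            ]
            return node
        return _LinNode("loss", sp, t)
    if sp.is_leaf:
        return _LinNode("leaf", sp, sp.age)
    node = _LinNode("spec", sp, sp.age)
    node.children = [
        _evolve_branch(child, sp.age, cfg, rng) for child in sp.children
    ]
    return node


def _collect_events(root: _LinNode) -> List[TrueEvent]:
    events = []
    stack = [root]
    while stack:
        ln = stack.pop()
        if ln.kind == "dup":
            events.append(TrueEvent("gain", ln.species.label, ln.age))
        elif ln.kind == "loss":
            events.append(TrueEvent("loss", ln.species.label, ln.age))
        stack.extend(ln.children)
    events.sort(key=lambda e: (-e.age, e.branch, e.kind))
    return events


def _prune_and_project(
    root: _LinNode, s: TimeTree, truth: SimulationTruth
) -> Optional[Node]:
    """Prune extinct lineages; record the observable event projection.

    Returns the observed gene-tree root (branch "lengths" are time spans in
    My) or None if the family went wholly extinct.  While pruning, the
    projection is accumulated in ``truth.obs_gains`` / ``truth.obs_losses``
    using only species-LCA algebra on surviving-species MRCAs.
    """

    def rec(ln: _LinNode) -> Optional[Tuple[Node, Node, float]]:
        # -> (observed gene node, species MRCA of survivors, node age)
        if ln.kind == "loss":
            return None
        if ln.kind == "leaf":
            node = Node(label=ln.species.label)  # copy index appended later
            return node, ln.species, ln.age
        results = [rec(c) for c in ln.children]
        alive = [r for r in results if r is not None]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        (n1, m1, a1), (n2, m2, a2) = alive
        m = s.lca(m1, m2)
        is_dup = (m is m1) or (m is m2)
        if is_dup:
            truth.obs_gains[m.label] += 1
        for mc in (m1, m2):
            walk = mc
            while walk is not m:
                parent = walk.parent
                if parent is m and not is_dup:
                    break
                truth.obs_losses[s.sibling(walk).label] += 1
                walk = parent
        v = Node()
        n1.length = ln.age - a1
        n2.length = ln.age - a2
        v.add_child(n1)
        v.add_child(n2)
        return v, m, ln.age

    out = rec(root)
    if out is None:
        truth.extinct = True
        return None
    node, m, age = out
    node.length = None
    # stem losses: subtrees hanging off the species-root -> MRCA path
    walk = m
    while walk.parent is not None:
        truth.obs_losses[s.sibling(walk).label] += 1
        walk = walk.parent
    return node


def simulate_gene_family(
    s: TimeTree, cfg: SimulationConfig, seed, og_id: str = "OG"
) -> Tuple[Optional[GeneTree], SimulationTruth]:
    """One gene family from a single copy at the species root.

    The returned gene tree carries *time spans in My* as branch lengths
    (convert with :func:`assign_branch_lengths`); ``None`` if the family
    went extinct everywhere.
    """
    rng = _rng(seed)
    truth = SimulationTruth(og_id=og_id)
    origin = _LinNode("spec", s.root, s.root_age)
    origin.children = [
        _evolve_branch(child, s.root_age, cfg, rng) for child in s.root.children
    ]
    truth.events = _collect_events(origin)
    observed = _prune_and_project(origin, s, truth)
    if observed is None:
        return None, truth
    counters: Dict[str, int] = {}
    for leaf in (n for n in observed.preorder() if n.is_leaf):
        sp = leaf.label
        counters[sp] = counters.get(sp, 0) + 1
        leaf.label = f"{sp}_{counters[sp]}"
    return GeneTree(observed, rooted=True), truth


def assign_branch_lengths(g: GeneTree, subst_rate: float, sigma_r: float, seed) -> GeneTree:
    """Convert time spans (My) to substitutions/site with a relaxed clock.

    l(b) = subst_rate * time(b) * eps_b, eps_b ~ lognormal(0, sigma_r^2);
    sigma_r = 0 gives a strict clock.
    """
    if subst_rate < 0:
        raise ValueError("substitution rate must be >= 0")
    rng = _rng(seed)
    out = GeneTree.from_newick(g.to_newick(), rooted=g.rooted)
    for node in out.postorder():
        if node.parent is None:
            continue
        eps = rng.lognormal(0.0, sigma_r) if sigma_r > 0 else 1.0
        node.length = subst_rate * (node.length or 0.0) * eps
    return out


def perturb_ils(g: GeneTree, ils_length: float, p_ils: float, seed) -> GeneTree:
    """Short-edge NNI noise emulating incomplete lineage sorting.

    Every internal edge shorter than ``ils_length`` is, with probability
    ``p_ils``, subjected to a random nearest-neighbour interchange and its
    length resampled uniformly on [0, ils_length].  Terminal edges and long
    internal edges are untouched.
    """
    if not 0.0 <= p_ils <= 1.0:
        raise ValueError("p_ils must be in [0, 1]")
    rng = _rng(seed)
    out = GeneTree.from_newick(g.to_newick(), rooted=g.rooted)
    if ils_length <= 0 or p_ils == 0:
        return out
    internal = [
        n for n in out.postorder()
        if n.parent is not None and not n.is_leaf and (n.length or 0.0) < ils_length
    ]
    changed = False
    for node in internal:
        if rng.random() >= p_ils:
            continue
        parent = node.parent
        if parent is None or len(parent.children) != 2 or len(node.children) != 2:
            continue
        sib_idx = 1 if parent.children[0] is node else 0
        sibling = parent.children[sib_idx]
        j = int(rng.integers(2))
        moved = node.children[j]
        # swap `moved` with `sibling` across the edge (parent, node)
        node.children[j] = sibling
        sibling.parent = node
        parent.children[sib_idx] = moved
        moved.parent = parent
        node.length = float(rng.uniform(0.0, ils_length))
        changed = True
    if changed:
        out._reindex()
    return out


def simulate_og_batch(
    s: TimeTree, cfg: SimulationConfig, seed=None, min_members: int = 4
) -> Tuple[List[OrthologGroup], List[SimulationTruth], int]:
    """A batch of gene families ready for reconciliation.

    Families are simulated, given relaxed-clock branch lengths and ILS
    noise, then filtered to groups with more than three members (the
    analysis condition).  Returns (groups, matching truths, number of
    families dropped as extinct or too small).
    """
    rng = _rng(cfg.seed if seed is None else seed)
    ogs: List[OrthologGroup] = []
    truths: List[SimulationTruth] = []
    dropped = 0
    for i in range(cfg.n_ogs):
        og_id = f"OG{i + 1:04d}"
        gtree, truth = simulate_gene_family(s, cfg, rng, og_id=og_id)
        if gtree is None or gtree.n_leaves < min_members:
            dropped += 1
            continue
        gtree = assign_branch_lengths(gtree, cfg.subst_rate, cfg.sigma_r, rng)
        gtree = perturb_ils(gtree, cfg.ils_length, cfg.p_ils, rng)
        ogs.append(OrthologGroup(og_id=og_id, tree=gtree))
        truths.append(truth)
    return ogs, truths, dropped


# ---------------------------------------------------------------------------
# presence matrices, traits, target-gene rates
# ---------------------------------------------------------------------------

def simulate_presence_matrix(
    species: Sequence[str] | int,
    n_ogs: int,
    seed,
    presence_prob_range: Tuple[float, float] = (0.2, 0.8),
) -> pd.DataFrame:
    """Independent Bernoulli presence/absence columns (single-copy OGs).

    Each column j has its own presence probability drawn uniformly from
    ``presence_prob_range``; rows are species.
    """
    rng = _rng(seed)
    if isinstance(species, int):
        species = [f"S{i + 1}" for i in range(species)]
    probs = rng.uniform(*presence_prob_range, size=n_ogs)
    data = (rng.random((len(species), n_ogs)) < probs).astype(int)
    cols = [f"OG{j + 1:04d}" for j in range(n_ogs)]
    return pd.DataFrame(data, index=list(species), columns=cols)


def simulate_traits(
    pm: pd.DataFrame,
    causal_set: Sequence[str],
    beta: float | Sequence[float],
    beta0: float,
    seed,
    name: str = "trait",
) -> Tuple[pd.Series, pd.Series]:
    """Binary trait ~ Bernoulli(logistic(beta0 + sum_j beta_j x_ij)).

    Returns (trait values, per-species probabilities).  Species are treated
    as independent given the presence matrix — no phylogenetic
    autocorrelation, matching the downstream non-phylogenetic regression.
    """
    rng = _rng(seed)
    causal_set = list(causal_set)
    missing = [c for c in causal_set if c not in pm.columns]
    if missing:
        raise ValueError(f"causal columns not in presence matrix: {missing}")
    betas = np.broadcast_to(np.asarray(beta, dtype=float), (len(causal_set),))
    for c in causal_set:
        if pm[c].nunique() < 2:
            warnings.warn(
                f"causal column {c!r} is constant across species (unidentifiable)"
            )
    eta = beta0 + pm[causal_set].to_numpy(dtype=float) @ betas
    probs = 1.0 / (1.0 + np.exp(-eta))
    values = (rng.random(len(pm)) < probs).astype(int)
    return (
        pd.Series(values, index=pm.index, name=name),
        pd.Series(probs, index=pm.index, name=f"{name}_prob"),
    )


def simulate_tg_rates(
    s: TimeTree,
    tf_absent: Set[str] | Sequence[str],
    base_rate: float,
    delta: float,
    sigma_g: float,
    seed,
) -> Tuple[pd.Series, GeneTree]:
    """Terminal target-gene rates with a deceleration in TF-lacking species.

    rate_i = base_rate * (1 - delta * I[i lacks the TF]) * eta_i with
    eta_i ~ lognormal(0, sigma_g^2).  Also emits a single-copy target-gene
    tree on the species topology whose terminal branch lengths equal
    rate_i * terminal duration (internal branches follow the base rate), so
    the round trip through rate estimation is exact when sigma_g = 0.
    """
    if not 0.0 <= delta < 1.0:
        raise ValueError("delta must be in [0, 1)")
    if base_rate < 0:
        raise ValueError("base_rate must be >= 0")
    rng = _rng(seed)
    tf_absent = set(tf_absent)
    unknown = [sp for sp in tf_absent if sp not in s]
    if unknown:
        raise ValueError(f"tf_absent species not in species tree: {unknown}")
    rates = {}
    for leaf in s.leaves:
        eta = rng.lognormal(0.0, sigma_g) if sigma_g > 0 else 1.0
        rates[leaf.label] = base_rate * (1.0 - delta * (leaf.label in tf_absent)) * eta
    series = pd.Series(rates, name="rate").sort_index()

    def build(sp: Node) -> Node:
        if sp.is_leaf:
            node = Node(label=f"{sp.label}_1")
            node.length = rates[sp.label] * (sp.parent.age - sp.age)
            return node
        node = Node()
        if sp.parent is not None:
            node.length = base_rate * (sp.parent.age - sp.age)
        for child in sp.children:
            node.add_child(build(child))
        return node

    return series, GeneTree(build(s.root), rooted=True)
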