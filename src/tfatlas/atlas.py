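"""Per-branch and time-windowed gain/loss rate atlases.

Reconciliation localises events to species-tree branches; the atlas sums
them over orthologous groups, divides by branch durations (My) to get
per-My rates, and smears events uniformly along branches to answer
windowed questions ("how fast was loss within 4 My of the K-Pg
boundary?").  Smearing is a convention, not an inference: reconciliation
says nothing about where on a branch an event happened.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .reconcile import Reconciliation
from .treeio import TimeTree, TreeError

logger = logging.getLogger(__name__)

__all__ = [
    "EventAtlas",
    "aggregate",
    "aggregate_event_table",
    "branch_rate",
    "window_rates",
    "lineage_mean_rate",
]


@dataclass
class EventAtlas:
    """Gain/loss counts and per-My rates on every species-tree branch.

    ``table`` has one row per branch (indexed by the branch's child-node
    label) with columns parent_age, child_age, duration, gains, losses,
    gain_rate, loss_rate.  The root itself has no branch; events mapped to
    the root node are kept in ``root_gains``/``root_losses`` so that event
    conservation holds exactly.
    """

    table: pd.DataFrame
    root_gains: int = 0
    root_losses: int = 0

    @property
    def total_gains(self) -> int:
        return int(self.table["gains"].sum()) + self.root_gains

    @property
    def total_losses(self) -> int:
        return int(self.table["losses"].sum()) + self.root_losses

    @property
    def total_events(self) -> int:
        return self.total_gains + self.total_losses

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True, index_label="branch")


def branch_rate(count: float, duration: float) -> float:
    """Events per My on one branch."""
    if duration <= 0:
        raise ValueError(f"branch duration must be positive, got {duration}")
    return count / duration


def aggregate(recs: Iterable[Reconciliation], s: TimeTree) -> EventAtlas:
    """Sum per-OG events into a per-branch atlas of counts and rates."""
    durations = s.branch_durations()
    gains = {b: 0 for b in durations}
    losses = {b: 0 for b in durations}
    root_label = s.root.label
    root_gains = root_losses = 0
    for rec in recs:
        for _, br in rec.duplications:
            if br == root_label:
                root_gains += 1
            elif br in gains:
                gains[br] += 1
            else:
                raise TreeError(f"unknown species branch {br!r} in {rec.og_id}")
        for br in rec.losses:
            if br == root_label:
                root_losses += 1
            elif br in losses:
                losses[br] += 1
            else:
                raise TreeError(f"unknown species branch {br!r} in {rec.og_id}")
    rows = []
    for node in s.postorder():
        if node.parent is None:
            continue
        b = node.label
        d = durations[b]
        rows.append(
            {
                "branch": b,
                "parent_age": node.parent.age,
                "child_age": node.age,
                "duration": d,
                "gains": gains[b],
                "losses": losses[b],
                "gain_rate": branch_rate(gains[b], d),
                "loss_rate": branch_rate(losses[b], d),
            }
        )
    table = pd.DataFrame(rows).set_index("branch")
    return EventAtlas(table=table, root_gains=root_gains, root_losses=root_losses)


def aggregate_event_table(events: pd.DataFrame, s: TimeTree) -> EventAtlas:
    """Atlas from a flat per-OG event table (og_id, event, branch).

    File-based twin of :func:`aggregate`, used when reconciliation output
    was written to TSV.
    """
    from .reconcile import Reconciliation

    recs = []
    for og_id, sub in events.groupby("og_id", sort=True):
        recs.append(
            Reconciliation(
                og_id=str(og_id),
                mapping={},
                duplications=[("", b) for b in sub.loc[sub["event"] == "gain", "branch"]],
                losses=list(sub.loc[sub["event"] == "loss", "branch"]),
            )
        )
    return aggregate(recs, s)


def window_rates(
    atlas: EventAtlas, s: TimeTree, window_edges: Sequence[float]
) -> pd.DataFrame:
    """Time-windowed gain/loss rates (events/My), windows in Mya.

    ``window_edges`` are ages sorted ascending; window w spans
    [edges[w], edges[w+1]].  Each branch's events are smeared uniformly
    over its duration, so a window receives count * overlap/duration from
    every overlapping branch; windowing the full span conserves totals.
    """
    edges = np.asarray(window_edges, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least two window edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("window edges must be strictly increasing (zero-width window)")
    t = atlas.table
    lo = t["child_age"].to_numpy()
    hi = t["parent_age"].to_numpy()
    dur = t["duration"].to_numpy()
    g = t["gains"].to_numpy(dtype=float)
    l = t["losses"].to_numpy(dtype=float)
    rows = []
    for w0, w1 in zip(edges[:-1], edges[1:]):
        overlap = np.clip(np.minimum(hi, w1) - np.maximum(lo, w0), 0.0, None)
        frac = overlap / dur
        width = w1 - w0
        rows.append(
            {
                "window_start": w0,
                "window_end": w1,
                "gains": float(g @ frac),
                "losses": float(l @ frac),
                "gain_rate": float(g @ frac) / width,
                "loss_rate": float(l @ frac) / width,
            }
        )
    return pd.DataFrame(rows)


def lineage_mean_rate(
    atlas: EventAtlas,
    s: TimeTree,
    epoch: Tuple[float, float],
    kind: str = "loss",
    duration_weighted: bool = False,
) -> float:
    """Mean per-branch rate over branches alive during an epoch (Mya).

    ``epoch = (older, younger)`` in Mya; a branch is alive if its age span
    overlaps the epoch (a degenerate epoch selects branches containing that
    time point).  The default is the unweighted arithmetic mean across
    alive branches; ``duration_weighted`` weights each branch by its
    overlap with the epoch.
    """
    older, younger = max(epoch), min(epoch)
    t = atlas.table
    col = {"gain": "gain_rate", "loss": "loss_rate"}[kind]
    lo = t["child_age"].to_numpy()
    hi = t["parent_age"].to_numpy()
    if older == younger:
        alive = (lo <= older) & (hi >= older)
        weights = np.ones_like(lo)
    else:
        overlap = np.clip(np.minimum(hi, older) - np.maximum(lo, younger), 0.0, None)
        alive = overlap > 0
        weights = overlap
    if not alive.any():
        raise ValueError(f"no branch alive in epoch {epoch}")
    rates = t[col].to_numpy()[alive]
    if duration_weighted:
        w = weights[alive]
        return float(np.average(rates, weights=w))
    return float(rates.mean())


def plot_atlas(atlas: EventAtlas, path=None):  # pragma: no cover - optional
    """Bar plot of per-branch gain/loss rates (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = atlas.table.sort_values("parent_age", ascending=False)
    fig, ax = plt.subplots(figsize=(8, 0.3 * len(t) + 1))
    y = np.arange(len(t))
    ax.barh(y - 0.2, t["gain_rate"], height=0.4, color="firebrick", label="gain/My")
    ax.barh(y + 0.2, -t["loss_rate"], height=0.4, color="steelblue", label="loss/My")
    ax.set_yticks(y)
    ax.set_yticklabels(t.index)
    ax.set_xlabel("events per My (losses to the left)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
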