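"""Target-gene terminal-branch rates and the paired deceleration test.

For every regulator-target (TF-TG) interaction, species are split into
those that still possess the TF (per the single-copy presence matrix) and
those that lost it.  The target gene's molecular rate in species *i* is its
terminal branch length (substitutions/site) divided by the species'
terminal branch duration (My).  Each interaction contributes one pair
(x, y) = (mean rate with TF, mean rate without TF); the deceleration
hypothesis says y < x on average, tested with a one-sample t test on
d = y - x (two-sided; a Wilcoxon signed-rank companion is reported as a
robustness check).

Interactions sharing a TG are kept as separate pairs (interaction-level
pairing) — a form of pseudo-replication, acknowledged; TG-level pairing
(averaging over a TG's regulators) is available via ``pair_by='tg'``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .treeio import GeneTree, TimeTree, split_leaf_label

logger = logging.getLogger(__name__)

__all__ = [
    "TGRatePair",
    "PairedTestResult",
    "terminal_rates",
    "pair_means",
    "paired_test",
    "deceleration_analysis",
]

MIN_GROUP_DEFAULT = 3


@dataclass(frozen=True)
class TGRatePair:
    tf_og_id: str
    tg_id: str
    rate_with: float  # mean terminal rate among TF-possessing species
    rate_without: float  # mean among TF-lacking species
    n_with: int
    n_without: int

    @property
    def diff(self) -> float:
        """without - with; negative under deceleration."""
        return self.rate_without - self.rate_with


@dataclass(frozen=True)
class PairedTestResult:
    t_stat: float
    p_value: float
    mean_diff: float
    n_pairs: int
    wilcoxon_stat: float
    wilcoxon_p: float


def terminal_rates(tg_tree: GeneTree, s: TimeTree) -> pd.Series:
    """Per-species terminal rate: branch length / branch duration (My).

    The TG tree must be single-copy in every species it contains; species
    missing from the TG tree are simply absent from the result.
    """
    counts = tg_tree.copy_counts()
    multi = [sp for sp, c in counts.items() if c > 1]
    if multi:
        raise ValueError(f"target-gene tree is not single-copy in: {multi}")
    rates = {}
    for leaf in tg_tree.leaves:
        sp, _ = split_leaf_label(leaf.label)
        sp_node = s.node(sp)
        if sp_node.parent is None:
            raise ValueError(f"species {sp} is the root; no terminal branch")
        duration = sp_node.parent.age - sp_node.age
        if duration <= 0:
            raise ValueError(f"non-positive terminal duration for {sp}")
        rates[sp] = (leaf.length or 0.0) / duration
    return pd.Series(rates, name="rate").sort_index()


def pair_means(
    rates: pd.Series,
    tf_presence: pd.Series,
    tf_og_id: str = "",
    tg_id: str = "",
    min_group: int = MIN_GROUP_DEFAULT,
) -> Optional[TGRatePair]:
    """Group-mean rates for one TF-TG pair, or None if a group is too small.

    ``tf_presence`` is a 0/1 series over species; only species present in
    both series are used.
    """
    common = rates.index.intersection(tf_presence.dropna().index)
    r = rates.loc[common]
    present = tf_presence.loc[common].astype(bool)
    with_tf = r[present]
    without_tf = r[~present]
    if len(with_tf) < min_group or len(without_tf) < min_group:
        return None
    return TGRatePair(
        tf_og_id=tf_og_id,
        tg_id=tg_id,
        rate_with=float(with_tf.mean()),
        rate_without=float(without_tf.mean()),
        n_with=len(with_tf),
        n_without=len(without_tf),
    )


def paired_test(pairs: Sequence[TGRatePair]) -> PairedTestResult:
    """One-sample t test of d = without - with against 0 (two-sided).

    d identically zero gives t = 0, p = 1.  The Wilcoxon signed-rank test
    is reported alongside as a distribution-free companion.
    """
    d = np.array([p.diff for p in pairs], dtype=float)
    if len(d) < 2:
        raise ValueError("need at least two pairs with finite differences")
    if np.allclose(d, 0.0):
        return PairedTestResult(0.0, 1.0, 0.0, len(d), 0.0, 1.0)
    t_stat, p = stats.ttest_1samp(d, 0.0)
    nz = d[d != 0]
    if len(nz) > 0:
        w_stat, w_p = stats.wilcoxon(nz)
    else:  # pragma: no cover - handled by allclose above
        w_stat, w_p = 0.0, 1.0
    return PairedTestResult(
        float(t_stat), float(p), float(d.mean()), len(d), float(w_stat), float(w_p)
    )


def deceleration_analysis(
    tg_trees: Dict[str, GeneTree],
    interactions: pd.DataFrame,
    presence: pd.DataFrame,
    s: TimeTree,
    min_group: int = MIN_GROUP_DEFAULT,
    pair_by: str = "interaction",
) -> Tuple[pd.DataFrame, PairedTestResult]:
    """Scatter table (x = rate with TF, y = rate without) and paired test.

    ``interactions`` has columns tf_og_id / tg_id; ``presence`` is the
    species x TF 0/1 matrix.  Interactions whose TF is absent from the
    presence matrix, whose TG has no tree, or whose groups fall below
    ``min_group`` are excluded and counted; used + excluded = input rows.
    """
    pairs: List[TGRatePair] = []
    excluded = 0
    rate_cache: Dict[str, pd.Series] = {}
    for row in interactions.itertuples(index=False):
        tf, tg = row.tf_og_id, row.tg_id
        if tf not in presence.columns or tg not in tg_trees:
            excluded += 1
            continue
        if tg not in rate_cache:
            rate_cache[tg] = terminal_rates(tg_trees[tg], s)
        pair = pair_means(
            rate_cache[tg], presence[tf], tf_og_id=tf, tg_id=tg, min_group=min_group
        )
        if pair is None:
            excluded += 1
            continue
        pairs.append(pair)
    logger.info(
        "deceleration analysis: %d pairs used, %d excluded of %d interactions",
        len(pairs), excluded, len(interactions),
    )
    if not pairs:
        raise ValueError("no valid TF-TG pairs after filtering")
    if pair_by == "tg":
        by_tg: Dict[str, List[TGRatePair]] = {}
        for p in pairs:
            by_tg.setdefault(p.tg_id, []).append(p)
        pairs = [
            TGRatePair(
                tf_og_id="+".join(sorted(q.tf_og_id for q in group)),
                tg_id=tg,
                rate_with=float(np.mean([q.rate_with for q in group])),
                rate_without=float(np.mean([q.rate_without for q in group])),
                n_with=min(q.n_with for q in group),
                n_without=min(q.n_without for q in group),
            )
            for tg, group in sorted(by_tg.items())
        ]
    elif pair_by != "interaction":
        raise ValueError("pair_by must be 'interaction' or 'tg'")
    scatter = pd.DataFrame(
        {
            "tf_og_id": [p.tf_og_id for p in pairs],
            "tg_id": [p.tg_id for p in pairs],
            "rate_with_tf": [p.rate_with for p in pairs],
            "rate_without_tf": [p.rate_without for p in pairs],
            "n_with": [p.n_with for p in pairs],
            "n_without": [p.n_without for p in pairs],
        }
    )
    return scatter, paired_test(pairs)
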