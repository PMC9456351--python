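"""Trait association: chi-square prescreen + L1 logistic regression.

Binary life-history traits are regressed on the presence/absence of
single-copy gene families across species.  Each family column is first
screened by a Pearson chi-square test on the 2x2 presence-by-trait table
(1 df, no continuity correction, p < alpha survives); the survivors enter
an L1-penalised logistic regression whose penalty is chosen by k-fold
cross-validated deviance.  A negative presence coefficient means the
*loss* of the family associates with trait = 1.

Species are treated as independent observations.  They are not: they share
phylogeny.  This mirrors the analysis being reproduced and a warning is
emitted on every run.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from .treeio import OrthologGroup, TimeTree

logger = logging.getLogger(__name__)

__all__ = [
    "PHYLO_WARNING",
    "AssociationResult",
    "build_single_copy_matrix",
    "chi2_screen",
    "lasso_path_lambda_max",
    "l1_logistic",
    "associate_trait",
]

PHYLO_WARNING = (
    "species are treated as independent observations; phylogenetic "
    "non-independence is NOT corrected"
)


def build_single_copy_matrix(
    ogs: Sequence[OrthologGroup], s: TimeTree
) -> pd.DataFrame:
    """Species x OG presence matrix restricted to single-copy families.

    A family qualifies when no species carries more than one copy;
    presence = 1 iff exactly one copy.  Columns constant across species
    carry no signal and are dropped.
    """
    species = sorted(s.leaf_labels)
    cols = {}
    for og in ogs:
        counts = og.member_counts
        if any(c > 1 for c in counts.values()):
            continue
        cols[og.og_id] = [1 if counts.get(sp, 0) == 1 else 0 for sp in species]
    pm = pd.DataFrame(cols, index=species)
    variable = pm.columns[pm.nunique() > 1]
    dropped = pm.shape[1] - len(variable)
    if dropped:
        logger.info("dropped %d constant presence columns", dropped)
    return pm[variable]


def chi2_screen(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray) -> Tuple[float, float]:
    """Pearson chi-square on the 2x2 table of x (presence) vs y (trait).

    1 df, no continuity correction.  Raises ``ValueError`` on a degenerate
    margin (constant x or y) — callers skip and log such columns.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    table = np.zeros((2, 2))
    for xi, yi in ((0, 0), (0, 1), (1, 0), (1, 1)):
        table[xi, yi] = np.sum((x == xi) & (y == yi))
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin in 2x2 table")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    assert dof == 1
    return float(stat), float(p)


def _standardize(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def lasso_path_lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest per-sample penalty at which all coefficients are zero.

    With standardized predictors and an unpenalised intercept,
    lambda_max = max_j |X_j' (y - ybar)| / n  (the KKT entry threshold of
    the penalised Bernoulli likelihood at the intercept-only fit).
    """
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    r = y - y.mean()
    return float(np.max(np.abs(Xs.T @ r)) / len(y))


def l1_logistic(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    lam: Optional[float] = None,
    k_folds: int = 10,
    n_lambdas: int = 40,
    rule: str = "min",
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 50_000,
) -> Tuple[np.ndarray, float, float]:
    """L1-penalised logistic regression; returns (coefs, intercept, lambda).

    Maximises (1/n) sum_i log-likelihood - lam * ||beta||_1 over
    column-standardized predictors with an unpenalised intercept
    (coefficients are reported on the standardized scale).  When ``lam`` is
    None it is chosen on a log-spaced path below the all-zero threshold by
    ``k_folds``-fold cross-validated deviance: the deviance minimiser
    (``rule='min'``) or the sparsest model within one standard error of it
    (``rule='1se'``).  ``lam = 0`` fits the unpenalised model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xs, _, _ = _standardize(X)
    if lam is not None and lam == 0:
        fit = LogisticRegression(
            penalty=None, solver="lbfgs", tol=1e-10, max_iter=max_iter
        ).fit(Xs, y)
        return fit.coef_.ravel(), float(fit.intercept_[0]), 0.0

    def fit_at(lam_value: float):
        C = 1.0 / (n * lam_value)
        return LogisticRegression(
            penalty="l1", solver="saga", C=C, tol=tol, max_iter=max_iter
        ).fit(Xs, y)

    if lam is None:
        lam_max = lasso_path_lambda_max(Xs, y)
        lams = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)
        Cs = 1.0 / (n * lams)
        # CV path at a loose tolerance (glmnet-style); tight refit below
        cv = LogisticRegressionCV(
            Cs=Cs,
            cv=k_folds,
            penalty="l1",
            solver="saga",
            scoring="neg_log_loss",
            tol=1e-3,
            max_iter=2000,
            random_state=seed,
            refit=False,
        ).fit(Xs, y)
        scores = cv.scores_[1.0]  # folds x Cs, higher = better
        mean_scores = scores.mean(axis=0)
        if rule == "min":
            best = int(np.argmax(mean_scores))
        elif rule == "1se":
            se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
            best_min = int(np.argmax(mean_scores))
            ok = mean_scores >= mean_scores[best_min] - se[best_min]
            best = int(np.flatnonzero(ok)[0])  # lams descend: first ok = sparsest
        else:
            raise ValueError("rule must be 'min' or '1se'")
        lam_chosen = float(lams[best])
        fit = fit_at(lam_chosen)
        return fit.coef_.ravel(), float(fit.intercept_[0]), lam_chosen
    fit = fit_at(lam)
    return fit.coef_.ravel(), float(fit.intercept_[0]), float(lam)


@dataclass
class AssociationResult:
    """Screen + fit summary for one trait."""

    trait: str
    table: pd.DataFrame  # per TF: chi2, p, survived, coefficient
    lam: float = float("nan")
    n_species: int = 0

    @property
    def selected(self) -> List[str]:
        sel = self.table.index[self.table["coefficient"].abs() > 0]
        return list(sel)

    @property
    def survivors(self) -> List[str]:
        return list(self.table.index[self.table["survived"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="tf_id")


def associate_trait(
    pm: pd.DataFrame,
    trait: pd.Series,
    alpha: float = 0.05,
    lam: Optional[float] = None,
    k_folds: int = 10,
    rule: str = "min",
    seed: int = 0,
) -> AssociationResult:
    """chi-square prescreen (p < alpha) then L1 logistic fit on survivors.

    Species with a missing trait value are dropped for this trait.  Columns
    with a degenerate 2x2 margin are skipped (p = NaN, logged).
    """
    warnings.warn(PHYLO_WARNING, stacklevel=2)
    common = pm.index.intersection(trait.dropna().index)
    pm = pm.loc[common]
    y = trait.loc[common].astype(int)
    rows = []
    for col in pm.columns:
        try:
            stat, p = chi2_screen(pm[col].to_numpy(), y.to_numpy())
        except ValueError:
            logger.info("column %s skipped in prescreen: degenerate margin", col)
            stat, p = float("nan"), float("nan")
        rows.append({"tf_id": col, "chi2": stat, "p": p})
    table = pd.DataFrame(rows, columns=["tf_id", "chi2", "p"]).set_index("tf_id")
    table["survived"] = table["p"] < alpha
    table["coefficient"] = 0.0
    survivors = list(table.index[table["survived"]])
    lam_used = float("nan")
    if survivors:
        coefs, intercept, lam_used = l1_logistic(
            pm[survivors], y, lam=lam, k_folds=k_folds, rule=rule, seed=seed
        )
        table.loc[survivors, "coefficient"] = coefs
    else:
        logger.info("trait %s: no prescreen survivors", trait.name)
    return AssociationResult(
        trait=str(trait.name), table=table, lam=lam_used, n_species=len(common)
    )
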