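"""Bootstrap stability selection of radiomics features with LASSO Cox.

A fixed plan of B bootstrap resamples of the training set (default B=1000,
each of training size, drawn with replacement) is shared by feature
selection and signature pooling.  Per resample: features with very high
pairwise |Spearman ρ| (> 0.90) are pruned by recursive elimination, then a
5-fold cross-validated LASSO Cox regression selects a support.  Supports
are pooled into a selection-frequency table (the *feature pool*); features
selected in at least ``cutoff`` resamples (default 500 of 1000) become the
candidates for signature pooling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .coxmath import as_time_event, cox_loglik_from_lp

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapPlan",
    "SelectionConfig",
    "make_bootstrap_plan",
    "prune_correlated",
    "lasso_cox_cv",
    "pool_and_threshold",
    "StabilityFeatureSelector",
]


@dataclass(frozen=True)
class SelectionConfig:
    corr_threshold: float = 0.90
    cv_folds: int = 5
    B: int = 1000
    pool_cutoff: int = 500
    cv_rule: str = "1se"  # penalty choice: "1se" (default) or "min"

    def validate(self):
        if not 0.0 < self.corr_threshold < 1.0:
            raise ValueError("corr_threshold must be in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.pool_cutoff > self.B:
            raise ValueError("pool_cutoff must be <= B")
        if self.cv_rule not in ("min", "1se"):
            raise ValueError("cv_rule must be 'min' or '1se'")


@dataclass(frozen=True)
class BootstrapPlan:
    """Immutable (B, n_train) index matrix of with-replacement resamples."""

    indices: np.ndarray
    seed: int

    def __post_init__(self):
        self.indices.setflags(write=False)

    @property
    def B(self):
        return self.indices.shape[0]

    @property
    def n_train(self):
        return self.indices.shape[1]


def make_bootstrap_plan(n_train: int, B: int = 1000, seed: int = 0) -> BootstrapPlan:
    if n_train < 2:
        raise ValueError("n_train must be >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_train, size=(B, n_train))
    return BootstrapPlan(indices=idx, seed=seed)


def _abs_spearman(X: np.ndarray) -> np.ndarray:
    """|Spearman ρ| matrix; undefined correlations (constant cols) -> 0."""
    p = X.shape[1]
    if p == 1:
        return np.zeros((1, 1))
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(X).statistic
    if p == 2:  # scipy returns a scalar for two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.nan_to_num(np.asarray(rho, dtype=float), nan=0.0)
    np.fill_diagonal(rho, 0.0)
    return np.abs(rho)


def prune_correlated(X: pd.DataFrame, threshold: float = 0.90) -> list:
    """Recursive elimination of highly rank-correlated features.

    While any pair exceeds the threshold, drop the feature with the most
    over-threshold partners (ties broken by larger mean |ρ|, then by
    lexicographically *later* name, so the alphabetically first of an
    identical pair survives).
    """
    names = list(X.columns)
    rho = _abs_spearman(X.to_numpy(dtype=float))
    alive = np.ones(len(names), dtype=bool)
    while True:
        over = (rho > threshold) & alive[:, None] & alive[None, :]
        deg = over.sum(axis=1)
        if deg.max(initial=0) == 0:
            break
        cand = np.flatnonzero(deg == deg.max())
        if len(cand) > 1:
            mean_rho = (rho * alive[None, :])[cand].sum(axis=1) / max(alive.sum() - 1, 1)
            cand = cand[mean_rho == mean_rho.max()]
            if len(cand) > 1:
                cand = [max(cand, key=lambda k: names[k])]
        alive[cand[0]] = False
    return [n for n, a in zip(names, alive) if a]


def _cv_loglik(beta, X, time, event, train_idx):
    """Verweij–van Houwelingen CV contribution: l(full) − l(train)."""
    lp = X @ beta
    return (cox_loglik_from_lp(lp, time, event)
            - cox_loglik_from_lp(lp[train_idx], time[train_idx], event[train_idx]))


def _group_folds(groups, folds, rng):
    """Fold assignment that keeps all copies of one source patient together.

    Bootstrap resamples contain duplicated patients; were duplicates allowed
    to straddle a CV fold boundary, the fold deviance would be evaluated on
    patients present in the fold's training part and the penalty choice would
    be wildly over-optimistic.  Folds are therefore drawn over *unique*
    source patients.
    """
    uniq = np.unique(groups)
    perm = rng.permutation(len(uniq))
    fold_of_uniq = {uniq[k]: perm[k] % folds for k in range(len(uniq))}
    return np.array([fold_of_uniq[g] for g in groups])


def lasso_cox_cv(X: pd.DataFrame, time, event, folds: int = 5, seed: int = 0,
                 n_alphas: int = 30, alpha_min_ratio: float = 0.05,
                 groups=None, cv_rule: str = "1se") -> list:
    """Support of a 5-fold cross-validated LASSO Cox fit.

    The L1 penalty path is fitted by coordinate descent on the Cox partial
    likelihood; fold deviance is the Verweij–van Houwelingen partial-
    likelihood difference.  ``cv_rule="min"`` takes the deviance-minimizing
    penalty; the default ``"1se"`` takes the strongest penalty within one
    standard error of that minimum, which keeps per-resample supports sparse
    enough for the frequency cutoff to separate real from lucky features.
    ``groups`` (source-patient ids, one per row) keeps bootstrap duplicates
    of a patient within one fold.
    """
    if cv_rule not in ("min", "1se"):
        raise ValueError("cv_rule must be 'min' or '1se'")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if event.sum() < 2:
        raise ValueError("need >= 2 events for LASSO Cox")
    # constant columns cannot enter the model
    keep = [c for c in X.columns if X[c].nunique() > 1]
    if not keep:
        return []
    Xk = X[keep].to_numpy(dtype=float)
    y = Surv.from_arrays(event, time)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=alpha_min_ratio, tol=1e-5)
    path.fit(Xk, y)
    alphas = path.alphas_  # descending
    cvl = np.full((folds, len(alphas)), np.nan)
    if groups is not None:
        fold_id = _group_folds(np.asarray(groups), folds,
                               np.random.default_rng(seed))
        splits = [np.flatnonzero(fold_id != k) for k in range(folds)]
    else:
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = [tr for tr, _ in kf.split(Xk)]
    for k, train_idx in enumerate(splits):
        if event[train_idx].sum() < 2:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, tol=1e-5)
        try:
            m.fit(Xk[train_idx], y[train_idx])
        except (ValueError, ArithmeticError):
            continue
        fitted = {a: i for i, a in enumerate(m.alphas_)}
        for ai, a in enumerate(alphas):
            if a in fitted:
                cvl[k, ai] = _cv_loglik(m.coef_[:, fitted[a]], Xk, time,
                                        event, train_idx)
    n_ok = np.sum(~np.isnan(cvl), axis=0)
    if n_ok.max() == 0:
        return []
    total = np.where(n_ok == n_ok.max(), np.nansum(cvl, axis=0), -np.inf)
    best = int(np.argmax(total))
    if cv_rule == "1se":
        with np.errstate(invalid="ignore"):
            se = np.nanstd(cvl, axis=0, ddof=1) * np.sqrt(n_ok.max())
        thr = total[best] - (se[best] if np.isfinite(se[best]) else 0.0)
        best = int(np.flatnonzero(total >= thr)[0])  # largest qualifying alpha
    beta = path.coef_[:, best]
    return [keep[k] for k in np.flatnonzero(beta != 0)]


def pool_and_threshold(supports, cutoff, feature_names=None):
    """Pool per-resample supports into counts; candidates have count ≥ cutoff.

    Returns ``(pool, candidates)`` where pool is a Series of selection counts
    sorted descending (name-ascending among ties) and candidates are the
    rank-ordered features at or above the cutoff ("selected fewer than
    ``cutoff`` times" means exclusion).
    """
    counts = {}
    for sup in supports:
        for f in sup:
            counts[f] = counts.get(f, 0) + 1
    if feature_names is not None:
        for f in feature_names:
            counts.setdefault(f, 0)
    pool = pd.Series(counts, dtype=int)
    pool = pool.sort_index().sort_values(ascending=False, kind="stable")
    candidates = list(pool.index[pool >= cutoff])
    return pool, candidates


class StabilityFeatureSelector(BaseEstimator):
    """Bootstrap-LASSO-Cox stability selector (sklearn-style).

    Parameters mirror :class:`SelectionConfig`; ``fit(X, y)`` expects a
    feature DataFrame and a survival outcome (``(time, event)`` tuple or a
    scikit-survival structured array).  Fitted attributes:

    ``feature_pool_``  selection counts per feature (Series, descending);
    ``candidates_``    rank-ordered features with count ≥ cutoff;
    ``supports_``      per-resample selected feature lists;
    ``plan_``          the bootstrap plan (shared with signature pooling);
    ``n_skipped_``     resamples skipped for having < 2 events (still count
                       toward the cutoff denominator B).
    """

    def __init__(self, B=1000, pool_cutoff=500, corr_threshold=0.90,
                 cv_folds=5, random_state=0, plan=None, cv_rule="1se"):
        self.B = B
        self.pool_cutoff = pool_cutoff
        self.corr_threshold = corr_threshold
        self.cv_folds = cv_folds
        self.random_state = random_state
        self.plan = plan
        self.cv_rule = cv_rule

    def fit(self, X: pd.DataFrame, y):
        SelectionConfig(self.corr_threshold, self.cv_folds, self.B,
                        self.pool_cutoff, self.cv_rule).validate()
        time, event = as_time_event(y)
        n = len(X)
        plan = self.plan or make_bootstrap_plan(n, self.B, self.random_state)
        if plan.n_train != n:
            raise ValueError("bootstrap plan size does not match X")
        supports = []
        n_skipped = 0
        for b in range(plan.B):
            idx = plan.indices[b]
            tb, eb = time[idx], event[idx]
            if eb.sum() < 2:
                n_skipped += 1
                supports.append([])
                logger.info("resample %d skipped: < 2 events", b)
                continue
            Xb = X.iloc[idx].reset_index(drop=True)
            retained = prune_correlated(Xb, self.corr_threshold)
            try:
                sup = lasso_cox_cv(Xb[retained], tb, eb, folds=self.cv_folds,
                                   seed=self.random_state + b, groups=idx,
                                   cv_rule=self.cv_rule)
            except ValueError:
                n_skipped += 1
                sup = []
            supports.append(sup)
        pool, candidates = pool_and_threshold(
            supports, self.pool_cutoff, feature_names=X.columns)
        self.feature_pool_ = pool
        self.candidates_ = candidates
        self.supports_ = supports
        self.plan_ = plan
        self.n_skipped_ = n_skipped
        self.status_ = "ok" if candidates else "empty-pool"
        return self

    def get_support(self):
        return [c in self.candidates_ for c in self.feature_pool_.index]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.candidates_]

    def pool_frame(self) -> pd.DataFrame:
        """Feature pool as a ``feature,count,frequency`` table."""
        return pd.DataFrame({
            "feature": self.feature_pool_.index,
            "count": self.feature_pool_.to_numpy(),
            "frequency": self.feature_pool_.to_numpy() / self.plan_.B,
        })
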