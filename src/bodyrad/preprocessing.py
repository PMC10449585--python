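"""Train/holdout splitting and train-only feature standardization.

The cohort is split 80:20, stratified by site so each center keeps the same
proportion in both subsets.  Continuous features are made approximately
Gaussian by a Yeo-Johnson power transform fitted per feature on the training
set (maximum likelihood over λ ∈ [-5, 5]), then centered and scaled to unit
SD; the identical frozen transform is applied to the holdout set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["SplitPlan", "split_cohort", "yeo_johnson", "YeoJohnsonScaler",
           "fit_transform_params", "apply_transform"]


@dataclass
class SplitPlan:
    train_ids: list
    holdout_ids: list
    fraction: float
    seed: int
    strata: dict = field(default_factory=dict)  # id -> stratum label

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))


def split_cohort(ids, strata=None, fraction=0.8, seed=0) -> SplitPlan:
    """Stratified random split; per-stratum training size = round(f·n)."""
    ids = list(ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 patients to split")
    if strata is None:
        strata = ["all"] * len(ids)
    strata = list(map(str, strata))
    rng = np.random.default_rng(seed)
    by = {}
    for i, s in zip(ids, strata):
        by.setdefault(s, []).append(i)
    train, hold = [], []
    for s in sorted(by):
        members = by[s]
        if len(members) < 2:
            warnings.warn(
                f"stratum {s!r} has {len(members)} patient(s); assigned to "
                "training", stacklevel=2)
            train.extend(members)
            continue
        perm = rng.permutation(len(members))
        n_train = int(round(fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train.extend(members[k] for k in perm[:n_train])
        hold.extend(members[k] for k in perm[n_train:])
    return SplitPlan(train_ids=train, holdout_ids=hold, fraction=fraction,
                     seed=seed, strata=dict(zip(ids, strata)))


def yeo_johnson(y, lam):
    """Yeo-Johnson power transform ψ(y; λ), vectorized over y.

    y ≥ 0: ((y+1)^λ − 1)/λ  (λ ≠ 0),  log(y+1)        (λ = 0)
    y < 0: −((1−y)^(2−λ) − 1)/(2−λ)  (λ ≠ 2),  −log(1−y) (λ = 2)
    """
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    pos = y >= 0
    if abs(lam) < 1e-12:
        out[pos] = np.log1p(y[pos])
    else:
        out[pos] = (np.power(y[pos] + 1.0, lam) - 1.0) / lam
    neg = ~pos
    if abs(lam - 2.0) < 1e-12:
        out[neg] = -np.log1p(-y[neg])
    else:
        out[neg] = -(np.power(1.0 - y[neg], 2.0 - lam) - 1.0) / (2.0 - lam)
    return out


def _fit_lambda(x, bounds=(-5.0, 5.0), xatol=1e-6):
    """Maximize the Yeo-Johnson Gaussian log-likelihood over λ (Brent)."""
    res = optimize.minimize_scalar(
        lambda lam: -stats.yeojohnson_llf(lam, x),
        bounds=bounds, method="bounded", options={"xatol": xatol},
    )
    return float(res.x)


def fit_transform_params(column, bounds=(-5.0, 5.0)):
    """Fit (λ, center, scale) on one training feature column.

    Requires ≥ 3 finite values with nonzero variance; raises otherwise.
    """
    x = np.asarray(column, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need >= 3 finite training values")
    if x.std() == 0:
        raise ValueError("constant column; excluded from modelling")
    lam = _fit_lambda(x, bounds)
    t = yeo_johnson(x, lam)
    center = float(t.mean())
    scale = float(t.std(ddof=1))
    if scale == 0:
        raise ValueError("degenerate transformed column")
    return {"lambda": lam, "center": center, "scale": scale}


def apply_transform(column, params):
    """Apply frozen (λ, center, scale); non-finite values propagate as NaN."""
    x = np.asarray(column, dtype=float)
    out = np.full_like(x, np.nan)
    ok = np.isfinite(x)
    out[ok] = (yeo_johnson(x[ok], params["lambda"]) - params["center"]) \
        / params["scale"]
    return out


class YeoJohnsonScaler(TransformerMixin, BaseEstimator):
    """Per-column Yeo-Johnson + center/scale transformer, train-only fit.

    Constant or too-sparse columns are recorded in ``excluded_`` and dropped
    from the transformed output.  Fitted parameters are frozen; ``transform``
    on holdout data never updates them.
    """

    def __init__(self, lmbda_bounds=(-5.0, 5.0), xatol=1e-6):
        self.lmbda_bounds = lmbda_bounds
        self.xatol = xatol

    def fit(self, X: pd.DataFrame, y=None):
        params, excluded = {}, []
        for col in X.columns:
            try:
                params[col] = fit_transform_params(X[col], self.lmbda_bounds)
            except ValueError as exc:
                excluded.append(col)
                warnings.warn(f"column {col!r} excluded: {exc}", stacklevel=2)
        self.params_ = params
        self.excluded_ = excluded
        self.columns_ = [c for c in X.columns if c in params]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in self.columns_:
            out[col] = apply_transform(X[col], self.params_[col])
        return pd.DataFrame(out, index=X.index)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"params": self.params_, "excluded": self.excluded_},
                      fh, indent=1)
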