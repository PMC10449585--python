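"""Signature pooling by backwards stepwise-AIC Cox, and named risk scores.

Over the same fixed bootstrap resamples used for feature selection, a
backwards stepwise Cox regression (objective: minimize AIC = 2k − 2·logPL)
reduces the candidate features to a per-resample set.  The frequency table
of those sets is the *signature pool*; the modal set becomes the signature
and an unpenalized Cox fit on the full training set supplies its
coefficients.  A score is the resulting linear predictor Σ βᵢ·xᵢ (log-hazard
units; higher = higher mortality hazard).

Shipped defaults reproduce the published clinical (C), body-composition (B)
and radiomics (R) score equations; they are frozen reference coefficients
fitted on the original patient cohort, not re-derivable from phantoms.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.base import BaseEstimator

from .coxmath import as_time_event, cox_newton_fit
from .radiomics import normalize_feature_name
from .selection import BootstrapPlan, make_bootstrap_plan

logger = logging.getLogger(__name__)

__all__ = [
    "stepwise_cox_aic",
    "pool_signatures",
    "select_signature",
    "FittedScore",
    "fit_final_score",
    "compute_score",
    "combine_scores",
    "SignatureCoxModel",
    "CLINICAL_SCORE",
    "BODYCOMP_SCORE",
    "RADIOMICS_SCORE",
    "CLINICAL_FEATURES",
    "BODYCOMP_FEATURES",
]

# a priori candidate sets for the non-radiomics signatures
CLINICAL_FEATURES = ("age", "bmi", "asa_ge3", "sex_male")
BODYCOMP_FEATURES = ("smra", "smi", "vati", "sati")


def _aic(loglik: float, k: int) -> float:
    return 2.0 * k - 2.0 * loglik


def stepwise_cox_aic(X: pd.DataFrame, time, event, candidates) -> tuple:
    """Backwards stepwise Cox selection minimizing AIC.

    Starts from the full candidate model and repeatedly removes the single
    feature whose removal most decreases the AIC; stops when no removal
    helps.  May return the empty set.  Non-convergent fits are retried with
    a tiny ridge stabilizer.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set is empty")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if event.sum() < 2:
        raise ValueError("need >= 2 events")

    _cache = {}

    def fit_ll(cols):
        key = tuple(cols)
        if key in _cache:
            return _cache[key]
        M = X[list(cols)].to_numpy(dtype=float)
        try:
            _, ll = cox_newton_fit(M, time, event)
        except np.linalg.LinAlgError:
            logger.info("ridge-stabilized refit for %s", cols)
            _, ll = cox_newton_fit(M, time, event, ridge=1e-6)
        _cache[key] = ll
        return ll

    current = list(candidates)
    aic_now = _aic(fit_ll(current), len(current))
    while current:
        best_drop, best_aic = None, aic_now
        for f in current:
            rest = [c for c in current if c != f]
            a = _aic(fit_ll(rest), len(rest))
            if a < best_aic - 1e-12:
                best_drop, best_aic = f, a
        if best_drop is None:
            break
        assert best_aic < aic_now, "AIC must decrease along accepted steps"
        current.remove(best_drop)
        aic_now = best_aic
    return tuple(current)


def pool_signatures(selected_sets) -> Counter:
    """Frequency table over canonical (sorted-name) feature sets."""
    return Counter(tuple(sorted(s)) for s in selected_sets if len(s) > 0)


def select_signature(pool: Counter) -> tuple:
    """Modal signature; ties → smaller set, then lexicographic order."""
    if not pool:
        return ()
    return min(pool.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))[0]


@dataclass
class FittedScore:
    """Named Cox linear predictor: feature names + log-hazard coefficients."""

    name: str
    features: tuple
    coefficients: tuple
    transform_ref: str | None = None  # identifies the frozen training transform
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.features) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")
        if not all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    def compute(self, X) -> pd.Series:
        return compute_score(self, X)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"name": self.name, "features": list(self.features),
                       "coefficients": list(self.coefficients),
                       "transform_ref": self.transform_ref,
                       "meta": self.meta}, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(name=d["name"], features=tuple(d["features"]),
                   coefficients=tuple(d["coefficients"]),
                   transform_ref=d.get("transform_ref"),
                   meta=d.get("meta", {}))


# Published score equations, shipped as frozen defaults.
CLINICAL_SCORE = FittedScore(
    name="C", features=("age", "asa_ge3", "sex_male"),
    coefficients=(0.01353, 0.4087, 0.2803),
    meta={"source": "published clinical score equation"},
)
BODYCOMP_SCORE = FittedScore(
    name="B", features=("vati",), coefficients=(0.1988,),
    meta={"source": "published body-composition score equation"},
)
RADIOMICS_SCORE = FittedScore(
    name="R",
    features=("SAT_original_shape2D_Perimeter",
              "VAT_original_glszm_SmallAreaEmphasis",
              "VAT_original_firstorder_Maximum"),
    coefficients=(0.3100, -0.2302, 0.1353),
    meta={"source": "published radiomics score equation",
          "aliases": ["SATI_original_shape2D_Perimeter",
                      "VATI_original_glszm_SmallAreaEmphasis",
                      "VATI_original_firstorder_Maximum"]},
)


def _resolve_column(X: pd.DataFrame, feature: str):
    if feature in X.columns:
        return X[feature]
    canon = normalize_feature_name(feature)
    if canon in X.columns:
        return X[canon]
    aliases = [c for c in X.columns if normalize_feature_name(c) == feature
               or normalize_feature_name(c) == canon]
    if aliases:
        return X[aliases[0]]
    return None


def compute_score(score: FittedScore, X) -> pd.Series:
    """Linear predictor Σ βᵢ·xᵢ per patient; missing features → NaN (logged)."""
    if isinstance(X, dict):
        X = pd.DataFrame([X])
    lp = pd.Series(0.0, index=X.index)
    for f, b in zip(score.features, score.coefficients):
        col = _resolve_column(X, f)
        if col is None:
            logger.warning("score %s: feature %r missing; score is NaN",
                           score.name, f)
            return pd.Series(np.nan, index=X.index)
        lp = lp + b * col.astype(float)
    lp.name = f"{score.name}_score"
    return lp


def fit_final_score(X: pd.DataFrame, time, event, features, name,
                    transform_ref=None) -> FittedScore:
    """Unpenalized Cox fit (Efron ties) of a feature set on full training data."""
    features = list(features)
    if not features:
        return FittedScore(name=name, features=(), coefficients=(),
                           transform_ref=transform_ref,
                           meta={"status": "empty-signature"})
    M = X[features]
    corr = M.corr().to_numpy()
    np.fill_diagonal(corr, 0.0)
    if np.any(np.abs(corr) > 1 - 1e-10):
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"singular design: features {features[i]!r} and {features[j]!r} "
            "are perfectly collinear")
    df = M.copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event).astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    coefs = tuple(float(cph.params_[f]) for f in features)
    return FittedScore(name=name, features=tuple(features), coefficients=coefs,
                       transform_ref=transform_ref,
                       meta={"loglik": float(cph.log_likelihood_)})


def combine_scores(component_lps: pd.DataFrame, time, event,
                   name: str) -> FittedScore:
    """Cox refit on component score linear predictors (e.g. CR, CB, CBR)."""
    return fit_final_score(component_lps, time, event,
                           list(component_lps.columns), name)


class SignatureCoxModel(BaseEstimator):
    """Signature pooling + final Cox fit as a fit/predict estimator.

    ``fit(X, y)`` runs backwards stepwise-AIC Cox over the resamples, pools
    the selected sets, picks the modal signature, and fits the final
    unpenalized Cox model on the full training data.  ``predict(X)`` returns
    the linear predictor (higher = higher hazard).

    resample_mode:
        "fixed-bootstrap" — the shared with-replacement bootstrap plan
        (default); "subsample75" — per-resample random 75% subsets without
        replacement, an alternative pooling scheme.
    """

    def __init__(self, candidates=None, B=1000, random_state=0, plan=None,
                 resample_mode="fixed-bootstrap", name="score"):
        self.candidates = candidates
        self.B = B
        self.random_state = random_state
        self.plan = plan
        self.resample_mode = resample_mode
        self.name = name

    def _resample_indices(self, n):
        if self.resample_mode == "fixed-bootstrap":
            plan = self.plan or make_bootstrap_plan(n, self.B, self.random_state)
            if plan.n_train != n:
                raise ValueError("bootstrap plan size does not match X")
            return plan, plan.indices
        if self.resample_mode == "subsample75":
            rng = np.random.default_rng(self.random_state)
            m = max(int(round(0.75 * n)), 2)
            idx = np.stack([rng.choice(n, size=m, replace=False)
                            for _ in range(self.B)])
            return None, idx
        raise ValueError(f"unknown resample_mode {self.resample_mode!r}")

    def fit(self, X: pd.DataFrame, y):
        time, event = as_time_event(y)
        candidates = (list(self.candidates) if self.candidates is not None
                      else list(X.columns))
        if not candidates:
            self.signature_ = ()
            self.signature_pool_ = Counter()
            self.plan_ = None
            self.score_ = FittedScore(self.name, (), (),
                                      meta={"status": "empty-signature"})
            self.coef_ = np.array([])
            self.status_ = "empty-signature"
            return self
        plan, indices = self._resample_indices(len(X))
        selected = []
        for b in range(indices.shape[0]):
            idx = indices[b]
            tb, eb = time[idx], event[idx]
            if eb.sum() < 2:
                logger.info("resample %d skipped: < 2 events", b)
                continue
            Xb = X.iloc[idx].reset_index(drop=True)
            usable = [c for c in candidates if Xb[c].nunique() > 1]
            if not usable:
                continue
            selected.append(stepwise_cox_aic(Xb, tb, eb, usable))
        self.plan_ = plan
        self.signature_pool_ = pool_signatures(selected)
        self.signature_ = select_signature(self.signature_pool_)
        self.score_ = fit_final_score(X, time, event, self.signature_,
                                      self.name)
        self.coef_ = np.asarray(self.score_.coefficients)
        self.status_ = "ok" if self.signature_ else "empty-signature"
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        if not self.signature_:
            return pd.Series(0.0, index=X.index, name=f"{self.name}_score")
        return compute_score(self.score_, X)

    def pool_frame(self) -> pd.DataFrame:
        rows = [{"signature": "+".join(sig), "count": cnt}
                for sig, cnt in self.signature_pool_.most_common()]
        return pd.DataFrame(rows, columns=["signature", "count"])
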