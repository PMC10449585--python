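"""Cox partial-likelihood primitives with Efron tie handling.

The stability-selection and signature-pooling stages refit Cox models
thousands of times on bootstrap resamples, so the partial likelihood, its
derivatives, and a Newton–Raphson fitter are implemented here as vectorized
numpy routines.  The final (reported) score fits go through lifelines; this
module is validated against lifelines in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cox_loglik_from_lp",
    "cox_loglik",
    "cox_newton_fit",
    "as_time_event",
]


def as_time_event(y):
    """Coerce survival outcome to ``(time, event)`` float/bool arrays.

    Accepts a ``(time, event)`` tuple, a 2-column array/DataFrame, or a
    scikit-survival structured array (event flag first or second field).
    """
    if isinstance(y, tuple) and len(y) == 2:
        time, event = y
    elif hasattr(y, "dtype") and y.dtype.names:
        names = y.dtype.names
        bool_field = [n for n in names if y.dtype[n] == np.bool_]
        if bool_field:
            event = y[bool_field[0]]
            time = y[[n for n in names if n != bool_field[0]][0]]
        else:  # fall back to sksurv's (event, time) ordering
            event, time = y[names[0]], y[names[1]]
    elif hasattr(y, "columns"):
        cols = {c.lower(): c for c in y.columns}
        time = y[cols.get("time", y.columns[0])]
        event = y[cols.get("event", y.columns[1])]
    else:
        arr = np.asarray(y)
        time, event = arr[:, 0], arr[:, 1]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if time.shape != event.shape:
        raise ValueError("time and event must have the same length")
    return time, event


def _efron_groups(time, event):
    """Sort ascending by time and locate event-time groups.

    Returns (order, group_start, group_dead_counts) where group_start indexes
    (in sorted order) the first subject with each distinct *event* time and
    dead counts are the number of events at that time.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    # distinct times and their first sorted position
    uniq, first = np.unique(t, return_index=True)
    counts = np.diff(np.append(first, t.size))
    # events per distinct time
    dead = np.add.reduceat(e.astype(np.int64), first) if t.size else np.array([], int)
    keep = dead > 0
    return order, first[keep], dead[keep], counts[keep]


def cox_loglik_from_lp(lp, time, event):
    """Efron log partial likelihood of a fixed linear predictor."""
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if not event.any():
        return 0.0
    order, starts, dead, _ = _efron_groups(time, event)
    lp_s = lp[order]
    e_s = event[order]
    # guard against overflow: partial likelihood is shift-invariant in lp
    shift = lp_s.max()
    w = np.exp(lp_s - shift)
    # risk-set sums: reverse cumulative sum evaluated at each group start
    rcum = np.cumsum(w[::-1])[::-1]
    s0_risk = rcum[starts]
    # tie-set sums and event lp sums per group
    we = np.where(e_s, w, 0.0)
    lpe = np.where(e_s, lp_s, 0.0)
    s0_tie = np.add.reduceat(we, starts)
    lp_sum = np.add.reduceat(lpe, starts)
    # Efron denominators: for l = 0..d-1, S0_risk - (l/d) * S0_tie
    d = dead
    total = 0.0
    # vectorize over all (group, l) pairs
    reps = np.repeat(np.arange(d.size), d)
    l_over_d = (np.concatenate([np.arange(k) for k in d]) / d[reps]) if d.size else np.array([])
    denom = s0_risk[reps] - l_over_d * s0_tie[reps]
    total = lp_sum.sum() - (np.log(denom).sum() + event.sum() * shift)
    return float(total)


def cox_loglik(X, beta, time, event):
    """Efron log partial likelihood at coefficient vector ``beta``."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    lp = X @ beta if X.ndim == 2 and X.shape[1] else np.zeros(len(time))
    return cox_loglik_from_lp(lp, time, event)


@np.errstate(over="ignore", divide="ignore", invalid="ignore")
def _loglik_grad_hess(X, beta, time, event, order, starts, dead):
    n, p = X.shape
    Xs = X[order]
    e_s = event[order]
    lp_s = Xs @ beta
    shift = lp_s.max() if n else 0.0
    w = np.exp(lp_s - shift)
    wX = w[:, None] * Xs
    wXX = wX[:, :, None] * Xs[:, None, :]  # (n, p, p)

    def revcum(a):
        return np.cumsum(a[::-1], axis=0)[::-1]

    s0r = revcum(w)[starts]
    s1r = revcum(wX)[starts]
    s2r = revcum(wXX.reshape(n, p * p))[starts].reshape(-1, p, p)

    emask = e_s
    s0t = np.add.reduceat(np.where(emask, w, 0.0), starts)
    s1t = np.add.reduceat(np.where(emask[:, None], wX, 0.0), starts)
    s2t = np.add.reduceat(
        np.where(emask[:, None], wXX.reshape(n, p * p), 0.0), starts
    ).reshape(-1, p, p)
    x_sum = np.add.reduceat(np.where(emask[:, None], Xs, 0.0), starts)
    lp_sum = np.add.reduceat(np.where(emask, lp_s, 0.0), starts)

    d = dead
    reps = np.repeat(np.arange(d.size), d)
    frac = np.concatenate([np.arange(k) for k in d]) / d[reps]
    den0 = s0r[reps] - frac * s0t[reps]                       # (m,)
    den1 = s1r[reps] - frac[:, None] * s1t[reps]              # (m, p)
    den2 = s2r[reps] - frac[:, None, None] * s2t[reps]        # (m, p, p)

    ll = lp_sum.sum() - np.log(den0).sum() - event.sum() * shift
    r1 = den1 / den0[:, None]
    grad = x_sum.sum(axis=0) - r1.sum(axis=0)
    hess = -(den2 / den0[:, None, None]).sum(axis=0) + np.einsum("mi,mj->ij", r1, r1)
    return float(ll), grad, hess


def cox_newton_fit(X, time, event, ridge=0.0, max_iter=50, tol=1e-9,
                   beta_cap=30.0):
    """Unpenalized (optionally ridge-stabilized) Cox fit by Newton–Raphson.

    Returns ``(beta, loglik)`` where ``loglik`` is the Efron log partial
    likelihood at the optimum (excluding any ridge term).  With zero columns
    the null model log likelihood is returned with an empty beta.  Monotone
    partial likelihoods (a covariate that perfectly orders the events, so the
    MLE is infinite) are cut off at ``|beta| = beta_cap``; the log likelihood
    is already at its asymptote to well under ``tol`` there.

    Raises
    ------
    np.linalg.LinAlgError
        if the (possibly ridge-stabilized) Hessian is singular.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n, p = X.shape
    if p == 0 or not event.any():
        return np.zeros(p), cox_loglik_from_lp(np.zeros(n), time, event)
    order, starts, dead, _ = _efron_groups(time, event)
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(X, beta, time, event, order, starts, dead)

    def pen(b, l):
        return l - 0.5 * ridge * (b @ b)

    for _ in range(max_iter):
        g = grad - ridge * beta
        h = hess - ridge * np.eye(p)
        step = np.linalg.solve(h, g)
        if not np.all(np.isfinite(step)):
            break
        obj = pen(beta, ll)
        alpha = 1.0
        for _ in range(10):  # step-halving line search
            cand = beta - alpha * step
            ll_c, grad_c, hess_c = _loglik_grad_hess(
                X, cand, time, event, order, starts, dead
            )
            if np.isfinite(ll_c) and pen(cand, ll_c) >= obj - 1e-12:
                break
            alpha *= 0.5
        else:
            break
        converged = abs(pen(cand, ll_c) - obj) < tol * (abs(obj) + 1.0)
        beta, ll, grad, hess = cand, ll_c, grad_c, hess_c
        if converged or np.abs(beta).max() > beta_cap:
            break
    return beta, ll
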