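"""Breslow partial-likelihood primitives.

These back three surfaces of the toolbox: the marginal partial-likelihood
screening utility, the marginal-Cox prefilter of the application pipeline,
and the test-set deviance.  Each works on the ordering V ascending with
risk set {k : V_k >= V_i} per event and Breslow handling of tied event
times.
"""

from __future__ import annotations

import warnings

import numpy as np


def _risk_index(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort permutation and, per subject, the start of its tie group.

    Returns ``order`` (ascending V) and ``group_start`` such that for the
    sorted arrays the risk set of subject ``i`` is ``slice(group_start[i], n)``.
    """
    order = np.argsort(V, kind="stable")
    v = V[order]
    _, start, inv = np.unique(v, return_index=True, return_inverse=True)
    return order, start[inv]


def breslow_loglik(eta: np.ndarray, V: np.ndarray, delta: np.ndarray) -> float:
    """Cox log partial likelihood at a fixed linear predictor (no fitting)."""
    eta = np.asarray(eta, dtype=float)
    if np.any(~np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    order, gstart = _risk_index(V)
    e = eta[order]
    d = np.asarray(delta)[order].astype(bool)
    # stabilise: subtract max before exponentiating
    c = e.max() if len(e) else 0.0
    rev = np.cumsum(np.exp(e - c)[::-1])[::-1]
    log_s0 = np.log(rev[gstart]) + c
    return float(np.sum(e[d] - log_s0[d]))


def null_loglik(V: np.ndarray, delta: np.ndarray) -> float:
    """Closed form at beta = 0: -sum over events of log(risk-set size)."""
    order, gstart = _risk_index(V)
    d = np.asarray(delta)[order].astype(bool)
    n = len(order)
    return float(-np.sum(np.log(n - gstart[d])))


def univariate_cox(
    x: np.ndarray,
    V: np.ndarray,
    delta: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-9,
) -> tuple[float, float, float]:
    """Newton–Raphson fit of the one-covariate Cox model.

    Returns ``(beta_hat, loglik_gain, se)`` where ``loglik_gain`` is
    ``l(beta_hat) - l(0) >= 0`` and ``se`` the inverse-information standard
    error.  A constant covariate yields ``(0, 0, inf)``.  Step-halving
    guards each Newton update; on non-convergence the best iterate is
    returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0, 0.0, np.inf
    order, gstart = _risk_index(V)
    xs = x[order]
    xs = xs - xs.mean()  # location does not change the partial likelihood
    d = np.asarray(delta)[order].astype(bool)
    n = len(xs)

    def suff(beta: float):
        w = np.exp(np.clip(beta * xs, -500, 500))
        s0 = np.cumsum(w[::-1])[::-1][gstart]
        s1 = np.cumsum((w * xs)[::-1])[::-1][gstart]
        s2 = np.cumsum((w * xs * xs)[::-1])[::-1][gstart]
        ll = float(np.sum(beta * xs[d] - np.log(s0[d])))
        m = s1 / s0
        score = float(np.sum(xs[d] - m[d]))
        info = float(np.sum(s2[d] / s0[d] - m[d] ** 2))
        return ll, score, info

    beta = 0.0
    ll, score, info = suff(beta)
    ll0 = ll
    best = (beta, ll, info)
    converged = False
    for _ in range(max_iter):
        if info <= 0:
            break
        step = score / info
        step = float(np.clip(step, -5.0, 5.0))
        # step-halving: insist on non-decreasing partial likelihood
        for _ in range(20):
            ll_new, score_new, info_new = suff(beta + step)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, score, info = beta + step, ll_new, score_new, info_new
        if ll > best[1]:
            best = (beta, ll, info)
        if abs(step) < tol:
            converged = True
            break
    if not converged and abs(score) > 1e-4 * max(1.0, abs(ll)):
        warnings.warn("marginal Cox fit did not converge; using best iterate", stacklevel=2)
    beta, ll, info = best
    se = np.sqrt(1.0 / info) if info > 0 else np.inf
    return float(beta), float(max(ll - ll0, 0.0)), float(se)
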