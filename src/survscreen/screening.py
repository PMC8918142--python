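"""Marginal (univariate) screening utilities for censored survival outcomes.

Seven utilities are provided, each mapping one covariate column and the
outcome pair ``(V, delta)`` to a non-negative score; features are ranked by
descending score:

* ``PL`` — gain in the marginal Cox partial likelihood at its maximiser;
* ``SIS`` — absolute Pearson correlation with log observed time
  (an ad hoc measure that ignores censoring);
* ``FAST`` — feature aberration at survival times: the averaged difference
  between a standardized covariate at each event and its at-risk mean;
* ``CINDEX`` — |Harrell's concordance − 1/2| of the covariate as risk score;
* ``IPCW_TAU`` — Kendall's tau over pairs, reweighted by the inverse squared
  Kaplan–Meier estimate of the censoring survivor function;
* ``RCDCS`` — distance correlation between the covariate's ECDF and the
  Kaplan–Meier CDF of survival time (robust, rank-based);
* ``CRCDCS`` — composite version of RCDCS over a quantile grid, comparing
  the covariate ECDF with IPCW-weighted survival-status indicators.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
from scipy import stats

from ._cox import univariate_cox
from .data import CensoringKM, ScreeningRanking, SurvivalData

__all__ = [
    "MARGINAL_METHODS",
    "censoring_km",
    "survival_km",
    "utility_pl",
    "utility_sis",
    "utility_fast",
    "utility_cindex",
    "utility_ipcw_tau",
    "utility_rcdcs",
    "utility_crcdcs",
    "distance_correlation",
    "concordance",
    "rank_features",
]

MARGINAL_METHODS = ("PL", "SIS", "FAST", "RCDCS", "CRCDCS", "CINDEX", "IPCW_TAU")

#: floor on G-hat inside IPCW weights; 1/floor^2 caps a single pair's weight
DEFAULT_G_FLOOR = 0.05


def censoring_km(V, delta) -> CensoringKM:
    """Kaplan–Meier estimate of the censoring survivor function G(t) = P(C > t)."""
    if np.asarray(delta).sum() == 0:
        warnings.warn("all observations censored: G-hat drops to 0", stacklevel=2)
    return CensoringKM.fit(V, delta)


def survival_km(V, delta) -> CensoringKM:
    """Kaplan–Meier estimate of the survival function S_T(t) = P(T > t)."""
    return CensoringKM.fit(V, 1 - np.asarray(delta))


def utility_pl(x, V, delta) -> float:
    """Marginal Cox partial-likelihood gain l(beta-hat) - l(0) >= 0."""
    _, gain, _ = univariate_cox(np.asarray(x, dtype=float), V, delta)
    return gain


def utility_sis(x, V, delta=None, log_time: bool = True) -> float:
    """|Pearson correlation| of the covariate with (log) observed time."""
    x = np.asarray(x, dtype=float)
    y = np.log(np.asarray(V, dtype=float)) if log_time else np.asarray(V, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def utility_fast(x, V, delta) -> float:
    """Feature aberration at survival times of the standardized covariate.

    FAST_j = (1/n) sum over events of (x_i - mean of x over the at-risk set
    {k : V_k >= V_i}); the absolute statistic is the utility.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return 0.0
    xs = (x - x.mean()) / sd
    return abs(_fast_raw(xs, V, delta))


def _fast_raw(x, V, delta) -> float:
    V = np.asarray(V, dtype=float)
    d = np.asarray(delta).astype(bool)
    order = np.argsort(V, kind="stable")
    xo, do = x[order], d[order]
    n = len(xo)
    _, start, inv = np.unique(V[order], return_index=True, return_inverse=True)
    gstart = start[inv]
    rev = np.cumsum(xo[::-1])[::-1]
    risk_mean = rev[gstart] / (n - gstart)
    return float(np.sum(xo[do] - risk_mean[do]) / n)


def concordance(score, V, delta) -> float:
    """Harrell's C of a risk score: higher score should accompany shorter time.

    Usable pairs have distinct observed times with the earlier one an event;
    ties in score count 1/2.  Returns NaN (with a warning) when no pair is
    usable.
    """
    num, den = _concordance_counts(np.asarray(score, dtype=float), V, delta)
    if den == 0:
        warnings.warn("no usable pairs for concordance", stacklevel=2)
        return float("nan")
    return num / den


def _concordance_counts(score, V, delta) -> tuple[float, float]:
    V = np.asarray(V, dtype=float)
    d = np.asarray(delta).astype(bool)
    # usable[i, k]: V_i < V_k and delta_i = 1
    usable = (V[:, None] < V[None, :]) & d[:, None]
    diff = score[:, None] - score[None, :]
    wins = usable * ((diff > 0) + 0.5 * (diff == 0))
    return float(wins.sum()), float(usable.sum())


def utility_cindex(x, V, delta) -> float:
    """|C - 1/2| so hazardous and protective features rank symmetrically."""
    c = concordance(x, V, delta)
    if np.isnan(c):
        return 0.0
    return abs(c - 0.5)


def _ipcw_pair_matrix(
    V, delta, G: CensoringKM, g_floor: float = DEFAULT_G_FLOOR
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Pairwise weight matrix W and sign(V_i - V_k), shared across features.

    W_ik = Delta_ik / G(min(V_i,V_k)-)^2 where Delta_ik indicates the pair's
    earlier subject is an event (0 on observed-time ties: such pairs carry
    sign 0 anyway).  G-hat is floored at ``g_floor`` so a tiny censoring
    survivor cannot let one pair dominate; the number of floored pairs is
    reported in diagnostics.
    """
    V = np.asarray(V, dtype=float)
    d = np.asarray(delta).astype(bool)
    sign_v = np.sign(V[:, None] - V[None, :])
    vmin = np.minimum(V[:, None], V[None, :])
    earlier_event = np.where(sign_v < 0, d[:, None], d[None, :]) & (sign_v != 0)
    g = G.left(vmin)
    capped = int(np.sum((g < g_floor) & earlier_event) // 2)
    g = np.maximum(g, g_floor)
    W = earlier_event / g**2
    np.fill_diagonal(W, 0.0)
    return W, sign_v, {"weight_capped_pairs": capped}


def utility_ipcw_tau(x, V, delta, G: CensoringKM | None = None) -> float:
    """|IPCW-weighted Kendall's tau| between the covariate and survival time.

    With no censoring every weight is 1 and the statistic reduces to the
    classical (tau-a) Kendall correlation.
    """
    if G is None:
        G = censoring_km(V, delta)
    W, sign_v, _ = _ipcw_pair_matrix(V, delta, G)
    return abs(_ipcw_tau_from_pairs(np.asarray(x, dtype=float), W, sign_v))


def _ipcw_tau_from_pairs(x, W, sign_v) -> float:
    n = len(x)
    sign_x = np.sign(x[:, None] - x[None, :])
    return float(np.sum(W * sign_v * sign_x) / (n * (n - 1)))


def distance_correlation(u, v, weights=None) -> float:
    """Sample distance correlation, optionally with subject weights.

    Double-centers the absolute-difference matrices; with weights the
    centering means are taken under the normalized weight measure.  Returns
    0 when either distance variance vanishes.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if len(u) != len(v) or len(u) < 2:
        raise ValueError("u and v must share a length >= 2")
    n = len(u)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        tot = w.sum()
        if tot <= 0:
            return 0.0
        w = w / tot
    A = _w_center(np.abs(u[:, None] - u[None, :]), w)
    B = _w_center(np.abs(v[:, None] - v[None, :]), w)
    ww = np.outer(w, w)
    dcov2 = float(np.sum(ww * A * B))
    du = float(np.sum(ww * A * A))
    dv = float(np.sum(ww * B * B))
    if du <= 0 or dv <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(du * dv)))


def _w_center(D: np.ndarray, w: np.ndarray) -> np.ndarray:
    row = D @ w
    grand = float(w @ row)
    return D - row[:, None] - row[None, :] + grand


def _ecdf(x: np.ndarray) -> np.ndarray:
    """Empirical CDF value at each point, rank/n with average ranks on ties."""
    return stats.rankdata(x, method="average") / len(x)


def utility_rcdcs(x, V, delta, S_T: CensoringKM | None = None) -> float:
    """Robust censored distance-correlation screening.

    Distance correlation between the covariate's empirical CDF and the
    Kaplan–Meier CDF of survival time evaluated at each observed time; fully
    rank-based in the covariate, hence invariant to monotone transforms.
    """
    if S_T is None:
        S_T = survival_km(V, delta)
    if len(S_T.jump_times) == 0:
        warnings.warn("degenerate survival KM (no events); RCDCS utility 0", stacklevel=2)
        return 0.0
    u = _ecdf(np.asarray(x, dtype=float))
    v = 1.0 - S_T(np.asarray(V, dtype=float))
    return distance_correlation(u, v)


def _km_quantile(S: CensoringKM, q: float) -> float | None:
    """Leftmost time where the KM CDF 1 - S reaches q; None on a plateau above."""
    cdf = 1.0 - S.surv_probs
    idx = np.searchsorted(cdf, q - 1e-12, side="left")
    if idx >= len(S.jump_times):
        return None
    return float(S.jump_times[idx])


def utility_crcdcs(
    x,
    V,
    delta,
    quantiles: Iterable[float] = (0.25, 0.5, 0.75),
    G: CensoringKM | None = None,
    S_T: CensoringKM | None = None,
) -> float:
    """Composite robust censored distance-correlation screening.

    For each grid quantile q the survival status 1{T > t_q} at the KM
    quantile t_q is compared with the covariate ECDF by weighted distance
    correlation.  A subject's status is determined (usable) when it is an
    event or was censored after t_q; usable subjects carry the
    inverse-probability-of-censoring weight 1 / G(min(V, t_q)-), the
    redistribute-to-the-right correction for censored mass.  The utility is
    the mean over usable grid points.
    """
    V = np.asarray(V, dtype=float)
    d = np.asarray(delta).astype(bool)
    if G is None:
        G = censoring_km(V, d.astype(int))
    if S_T is None:
        S_T = survival_km(V, d.astype(int))
    u = _ecdf(np.asarray(x, dtype=float))
    vals = []
    for q in quantiles:
        if not 0 < q < 1:
            raise ValueError("quantile grid must lie in (0, 1)")
        tq = _km_quantile(S_T, q)
        if tq is None:
            warnings.warn(f"KM plateau below quantile {q}; dropped from composite", stacklevel=2)
            continue
        psi = (V > tq).astype(float)
        usable = d | (V > tq)
        w = np.where(usable, 1.0 / np.maximum(G.left(np.minimum(V, tq)), DEFAULT_G_FLOOR), 0.0)
        vals.append(distance_correlation(u, psi, weights=w))
    if not vals:
        return 0.0
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# whole-table ranking


def rank_features(data: SurvivalData, method: str, **options) -> ScreeningRanking:
    """Apply one marginal utility to every feature and rank descending.

    The censoring and survival Kaplan–Meier estimates and, for IPCW tau,
    the pairwise weight matrix are computed once and shared across all p
    features.  Ties in utility break by ascending feature id.
    """
    method = method.upper().replace("-", "_")
    if method not in MARGINAL_METHODS:
        raise ValueError(f"unknown screening method {method!r}; choose from {MARGINAL_METHODS}")
    X, V, delta = data.X, data.V, data.delta
    p = data.p
    utils = np.zeros(p)
    diagnostics: dict = {}
    if method == "IPCW_TAU":
        G = censoring_km(V, delta)
        W, sign_v, diagnostics = _ipcw_pair_matrix(
            V, delta, G, options.get("g_floor", DEFAULT_G_FLOOR)
        )
        M = W * sign_v
        for j in range(p):
            xj = X[:, j]
            utils[j] = abs(float(np.sum(M * np.sign(xj[:, None] - xj[None, :]))
                                / (data.n * (data.n - 1))))
    elif method == "PL":
        for j in range(p):
            utils[j] = utility_pl(X[:, j], V, delta)
    elif method == "SIS":
        log_time = options.get("log_time", True)
        for j in range(p):
            utils[j] = utility_sis(X[:, j], V, log_time=log_time)
    elif method == "FAST":
        for j in range(p):
            utils[j] = utility_fast(X[:, j], V, delta)
    elif method == "CINDEX":
        for j in range(p):
            utils[j] = utility_cindex(X[:, j], V, delta)
    elif method == "RCDCS":
        S_T = survival_km(V, delta)
        for j in range(p):
            utils[j] = utility_rcdcs(X[:, j], V, delta, S_T=S_T)
    elif method == "CRCDCS":
        G = censoring_km(V, delta)
        S_T = survival_km(V, delta)
        grid = options.get("quantiles", (0.25, 0.5, 0.75))
        for j in range(p):
            utils[j] = utility_crcdcs(X[:, j], V, delta, quantiles=grid, G=G, S_T=S_T)
    return ScreeningRanking(utilities=utils, method=method, diagnostics=diagnostics)
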