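"""Core data containers shared across the screening toolbox.

The universal input is a right-censored survival sample: an ``n x p``
covariate table ``X``, observed times ``V_i = min(T_i, C_i)`` and event
indicators ``delta_i = 1{T_i <= C_i}``.  Screening methods return a
:class:`ScreeningRanking` — per-feature utilities together with the induced
descending-order permutation of feature ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SurvivalData:
    """Right-censored survival sample.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Covariate table, no missing values.
    V : ndarray of shape (n,)
        Observed times ``min(T, C)``, strictly positive.
    delta : ndarray of shape (n,)
        Event indicators, 1 = event observed, 0 = right-censored.
    feature_names : list of str, optional
        Column labels; defaults to ``f0 .. f{p-1}``.
    """

    X: np.ndarray
    V: np.ndarray
    delta: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d samples x features table")
        self.V = np.asarray(self.V, dtype=float).ravel()
        self.delta = np.asarray(self.delta, dtype=int).ravel()
        n = self.X.shape[0]
        if self.V.shape[0] != n or self.delta.shape[0] != n:
            raise ValueError("X, V and delta disagree on the number of subjects")
        if n < 3:
            raise ValueError("need at least 3 subjects")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if np.any(self.V <= 0):
            raise ValueError("observed times must be strictly positive")
        if not np.isin(self.delta, (0, 1)).all():
            raise ValueError("delta must be 0/1")
        if self.delta.sum() == 0:
            raise ValueError("need at least one observed event")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        elif len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must equal p")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset_features(self, idx: np.ndarray) -> "SurvivalData":
        idx = np.asarray(idx, dtype=int)
        return SurvivalData(
            self.X[:, idx],
            self.V,
            self.delta,
            [self.feature_names[j] for j in idx],
        )

    def subset_subjects(self, idx: np.ndarray) -> "SurvivalData":
        idx = np.asarray(idx)
        return SurvivalData(self.X[idx], self.V[idx], self.delta[idx], list(self.feature_names))


class CensoringKM:
    """Kaplan–Meier estimate of the censoring survivor function G(t) = P(C > t).

    Built by treating censorings (``delta = 0``) as the event of interest;
    at tied times deaths precede censorings, i.e. subjects failing at ``t``
    remain in the risk set for a censoring at ``t``.  Supports both
    right-continuous evaluation ``G(t)`` and the left limit ``G(t-)`` needed
    by inverse-probability-of-censoring weights.
    """

    def __init__(self, jump_times: np.ndarray, surv_probs: np.ndarray):
        self.jump_times = np.asarray(jump_times, dtype=float)
        self.surv_probs = np.asarray(surv_probs, dtype=float)
        if np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if np.any(np.diff(self.surv_probs) > 1e-12):
            raise ValueError("survivor probabilities must be non-increasing")

    @classmethod
    def fit(cls, V: np.ndarray, delta: np.ndarray) -> "CensoringKM":
        V = np.asarray(V, dtype=float)
        delta = np.asarray(delta, dtype=int)
        order = np.argsort(V, kind="stable")
        v, d = V[order], delta[order]
        times, start, inv = np.unique(v, return_index=True, return_inverse=True)
        n = len(v)
        at_risk = n - start  # #{V_k >= t}: deaths at t stay at risk for censorings at t
        n_cens = np.bincount(inv, weights=(d == 0).astype(float), minlength=len(times))
        keep = n_cens > 0
        factors = 1.0 - n_cens[keep] / at_risk[keep]
        probs = np.cumprod(factors)
        return cls(times[keep], probs)

    def __call__(self, t) -> np.ndarray:
        """Right-continuous G(t)."""
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="right")
        return np.concatenate(([1.0], self.surv_probs))[idx]

    def left(self, t) -> np.ndarray:
        """Left limit G(t-)."""
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="left")
        return np.concatenate(([1.0], self.surv_probs))[idx]


@dataclass
class ScreeningRanking:
    """Per-feature utilities and the induced descending ranking.

    ``order[r]`` is the feature id at rank ``r`` (0-based); ties in utility
    are broken by ascending feature id so rankings are deterministic.
    """

    utilities: np.ndarray
    method: str
    order: np.ndarray = field(init=False)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.utilities = np.asarray(self.utilities, dtype=float)
        if np.any(~np.isfinite(self.utilities)):
            raise ValueError("utilities must be finite")
        p = len(self.utilities)
        # lexsort: primary key descending utility, secondary ascending id
        self.order = np.lexsort((np.arange(p), -self.utilities))

    @property
    def p(self) -> int:
        return len(self.utilities)

    def top(self, k: int) -> np.ndarray:
        """Feature ids of the top-``k`` ranked features."""
        return self.order[: min(k, self.p)]

    def ranks(self) -> np.ndarray:
        """1-based rank of each feature id."""
        r = np.empty(self.p, dtype=int)
        r[self.order] = np.arange(1, self.p + 1)
        return r
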