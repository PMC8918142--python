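"""Synthetic survival cohorts from a linear transformation model.

Cohorts follow ``H(T) = -x'beta + eps`` with the monotone transform
``H(t) = log(0.5 (exp(2 t) - 1))``.  A standard extreme-value error gives a
proportional-hazards (PH) model; a standard logistic error gives
proportional odds (PO).  Covariates are mean-zero Gaussian with one of five
network-structured correlation matrices (AR(1), band, hub, cluster,
scale-free), optionally contaminated entrywise by heavy-tailed Student-t
draws.  Censoring times are uniform on (0, b) with ``b`` calibrated by
Monte-Carlo bisection to hit a target censoring proportion.

Three ready-made study designs are exposed through :func:`scenario_config`:

* ``sim1`` — AR(1) correlation, sparse linear effects with 14 true predictors;
* ``sim2`` — same coefficients, but four of the true features act through
  nonlinear links (|x|, x^2, 1{x > 0});
* ``sim3`` — network-structured correlation (hub/band/cluster/scale-free)
  with a +-1.5 coefficient vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import networkx as nx
import numpy as np
import scipy.sparse
import scipy.sparse.linalg

__all__ = [
    "NetworkSpec",
    "EffectSpec",
    "ErrorModel",
    "CensoringSpec",
    "ContaminationSpec",
    "SimulatedCohort",
    "ScenarioConfig",
    "transform_H",
    "transform_H_inv",
    "build_beta",
    "build_links",
    "generate_network_covariance",
    "draw_covariates",
    "contaminate",
    "linear_predictor",
    "draw_errors",
    "draw_survival",
    "active_set_sampler",
    "calibrate_censoring",
    "draw_outcomes",
    "simulate",
    "scenario_config",
]

Structure = Literal["ar1", "band", "hub", "cluster", "scale_free"]
Link = Literal["linear", "abs", "square", "indicator_positive"]


# ---------------------------------------------------------------------------
# specification dataclasses


@dataclass(frozen=True)
class NetworkSpec:
    """Gene-network correlation structure for the covariates."""

    structure: Structure = "ar1"
    p: int = 2000
    rho: float = 0.5
    bandwidth: int = 1
    group_size: int = 20
    edge_prob: float = 0.3
    attach_m: int = 1
    offdiag_v: float = 0.3
    diag_u: float = 0.1

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")
        if self.bandwidth < 1 or self.group_size < 1 or self.attach_m < 1:
            raise ValueError("bandwidth, group_size and attach_m must be positive")
        if not 0 < self.edge_prob <= 1:
            raise ValueError("edge_prob must lie in (0, 1]")


@dataclass(frozen=True)
class EffectSpec:
    """Sparse effect vector beta with optional per-feature link functions."""

    beta: np.ndarray
    links: tuple[Link, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.links is not None and len(self.links) != len(self.beta):
            raise ValueError("links length must equal beta length")

    @property
    def p(self) -> int:
        return len(self.beta)

    @property
    def support(self) -> np.ndarray:
        """0-based indices of true predictors (nonzero beta)."""
        return np.flatnonzero(self.beta != 0)


@dataclass(frozen=True)
class ErrorModel:
    """Transformation-model error family.

    ``extreme_value_ph``: CDF 1 - exp(-e^u) (so H(T) = -x'beta + eps is a
    proportional-hazards model); ``logistic_po``: standard logistic CDF,
    the proportional-odds model.
    """

    family: Literal["extreme_value_ph", "logistic_po"] = "extreme_value_ph"

    def __post_init__(self) -> None:
        if self.family not in ("extreme_value_ph", "logistic_po"):
            raise ValueError(f"unknown error family {self.family!r}")


@dataclass(frozen=True)
class CensoringSpec:
    """Uniform censoring C ~ U(a, b)."""

    a: float = 0.0
    b: float = 1.0
    target_rate: float | None = None

    def __post_init__(self) -> None:
        if self.a < 0 or self.b <= self.a:
            raise ValueError("need 0 <= a < b < inf")
        if not np.isfinite(self.b):
            raise ValueError("b must be finite")


@dataclass(frozen=True)
class ContaminationSpec:
    """Entrywise heavy-tailed contamination of the covariate table."""

    prob: float = 0.1
    df: float = 2.0
    per_subject: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.prob <= 1:
            raise ValueError("prob must lie in [0, 1]")
        if self.df <= 0:
            raise ValueError("df must be positive")


@dataclass
class SimulatedCohort:
    """A generated cohort plus the latent truth used for evaluation."""

    X: np.ndarray
    V: np.ndarray
    delta: np.ndarray
    T_true: np.ndarray
    C_true: np.ndarray
    truth: np.ndarray
    adjacency: list[tuple[int, int]]
    contaminated_mask: np.ndarray
    censoring: CensoringSpec | None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_survival_data(self):
        from .data import SurvivalData

        return SurvivalData(self.X, self.V, self.delta)


# ---------------------------------------------------------------------------
# transformation model


def transform_H(t):
    """Monotone transform H(t) = log(0.5 (exp(2t) - 1)), defined for t > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("H(t) requires t > 0")
    # log(0.5 (e^{2t} - 1)) = 2t + log(0.5) + log1p(-exp(-2t)), stable for large t
    out = 2.0 * t + np.log(0.5) + np.log1p(-np.exp(-2.0 * t))
    return out if out.ndim else float(out)


def transform_H_inv(u):
    """Analytic inverse of :func:`transform_H`: t = 0.5 log(1 + 2 e^u)."""
    u = np.asarray(u, dtype=float)
    # split at 0 to avoid overflow of exp at either extreme
    pos = 0.5 * (u + np.log(2.0 + np.exp(-np.maximum(u, 0.0))))
    neg = 0.5 * np.log1p(2.0 * np.exp(np.minimum(u, 0.0)))
    out = np.where(u > 0, pos, neg)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# effect vectors

_BETA_HEAD_SIM1 = (
    -1.0, -0.9, 0.5, 0.8, 0.6,
    0.0, 0.0, 0.0, 0.0, 0.0,
    0.3, 0.7, -0.8, -0.5, -1.0,
    0.0, 0.0, 0.0, 0.0, 0.0,
    -2.0, 1.0, 0.0, -0.5, -2.0,
)

_BETA_HEAD_SIM3 = (
    -1.5, -1.5, 1.5, 1.5, 1.5,
    0.0, 0.0, 0.0, 0.0, 0.0,
    1.5, 1.5, -1.5, -1.5, -1.5,
    0.0, 0.0, 0.0, 0.0, 0.0,
    -1.5, 1.5, 1.5, -1.5, -1.5,
)

# nonlinear links of the second design (0-based feature index)
_SIM2_LINKS: dict[int, Link] = {0: "abs", 1: "abs", 3: "square", 4: "indicator_positive"}


def build_beta(scenario: str, p: int = 2000) -> EffectSpec:
    """Sparse coefficient vector of the first or third study design."""
    if scenario == "sim1":
        head = _BETA_HEAD_SIM1
    elif scenario == "sim3":
        head = _BETA_HEAD_SIM3
    else:
        raise ValueError(f"unknown scenario {scenario!r}; expected 'sim1' or 'sim3'")
    if p < len(head):
        raise ValueError(f"p must be >= {len(head)}")
    beta = np.zeros(p)
    beta[: len(head)] = head
    return EffectSpec(beta=beta)


def build_links(p: int = 2000) -> EffectSpec:
    """Second design: sim1 coefficients with nonlinear links on 4 true features."""
    base = build_beta("sim1", p)
    links = tuple(_SIM2_LINKS.get(j, "linear") for j in range(p))
    return EffectSpec(beta=base.beta, links=links)


def apply_link(link: Link, beta_j: float, x: np.ndarray) -> np.ndarray:
    if link == "linear":
        return beta_j * x
    if link == "abs":
        return beta_j * np.abs(x)
    if link == "square":
        return beta_j * x**2
    if link == "indicator_positive":
        return beta_j * (x > 0).astype(float)
    raise ValueError(f"unknown link {link!r}")


def linear_predictor(X: np.ndarray, effects: EffectSpec) -> np.ndarray:
    """eta_i = sum_j g_j(x_ij); reduces to X beta when all links are linear."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != effects.p:
        raise ValueError(f"X has {X.shape[1]} columns but beta has length {effects.p}")
    if effects.links is None:
        return X @ effects.beta
    eta = np.zeros(X.shape[0])
    for j in np.flatnonzero(effects.beta != 0):
        eta += apply_link(effects.links[j], effects.beta[j], X[:, j])
    return eta


# ---------------------------------------------------------------------------
# network covariance


def _adjacency(spec: NetworkSpec, rng: np.random.Generator) -> scipy.sparse.csr_matrix:
    p = spec.p
    if spec.structure == "band":
        rows, cols = [], []
        for w in range(1, spec.bandwidth + 1):
            rows.extend(range(p - w))
            cols.extend(range(w, p))
    elif spec.structure == "hub":
        rows, cols = [], []
        for g0 in range(0, p, spec.group_size):
            for k in range(g0 + 1, min(g0 + spec.group_size, p)):
                rows.append(g0)
                cols.append(k)
    elif spec.structure == "cluster":
        rows, cols = [], []
        for g0 in range(0, p, spec.group_size):
            members = range(g0, min(g0 + spec.group_size, p))
            for j in members:
                for k in members:
                    if k > j and rng.random() < spec.edge_prob:
                        rows.append(j)
                        cols.append(k)
    elif spec.structure == "scale_free":
        g = nx.barabasi_albert_graph(p, spec.attach_m, seed=int(rng.integers(2**31)))
        rows, cols = zip(*((min(e), max(e)) for e in g.edges())) if g.edges() else ([], [])
        rows, cols = list(rows), list(cols)
    else:
        raise ValueError(f"no adjacency builder for structure {spec.structure!r}")
    data = np.ones(len(rows))
    A = scipy.sparse.coo_matrix((data, (rows, cols)), shape=(p, p))
    return (A + A.T).tocsr()


def generate_network_covariance(
    spec: NetworkSpec, seed: int | None = None
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Unit-diagonal covariance and generating edge set for a network spec.

    AR(1) is analytic: cov[j, k] = rho^|j-k| with chain adjacency.  The four
    graph structures build a 0/1 adjacency A, form the precision
    ``Omega = v A + (|lambda_min(v A)| + 0.1 + u) I`` and return the inverse
    rescaled to correlation form — the construction used by standard
    Gaussian graphical-model simulators.
    """
    rng = np.random.default_rng(seed)
    p = spec.p
    if spec.structure == "ar1":
        idx = np.arange(p)
        cov = spec.rho ** np.abs(idx[:, None] - idx[None, :])
        edges = [(j, j + 1) for j in range(p - 1)]
        return cov, edges
    A = _adjacency(spec, rng)
    vA = spec.offdiag_v * A
    if p > 3:
        lam_min = scipy.sparse.linalg.eigsh(
            vA.astype(float), k=1, which="SA", return_eigenvectors=False,
            maxiter=5000, v0=np.full(p, 1.0 / np.sqrt(p)),
        )[0]
    else:
        lam_min = np.linalg.eigvalsh(vA.toarray()).min()
    omega = vA.toarray() + (abs(lam_min) + 0.1 + spec.diag_u) * np.eye(p)
    # positive definite by construction: diagonal exceeds |lambda_min| of the off-diagonal part
    cov = np.linalg.inv(omega)
    dsq = np.sqrt(np.diag(cov))
    cov = cov / np.outer(dsq, dsq)
    cov = (cov + cov.T) / 2.0
    assert np.all(np.linalg.eigvalsh(omega) > 0), "precision lost positive definiteness"
    upper = scipy.sparse.triu(A, k=1).tocoo()
    edges = sorted(zip(upper.row.tolist(), upper.col.tolist()))
    return cov, edges


def draw_covariates(n: int, covariance: np.ndarray, seed: int | None = None) -> np.ndarray:
    """n i.i.d. mean-zero Gaussian rows with the given covariance (Cholesky)."""
    rng = np.random.default_rng(seed)
    try:
        L = np.linalg.cholesky(np.asarray(covariance, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance of shape {np.shape(covariance)} is not positive definite"
        ) from exc
    Z = rng.standard_normal((n, covariance.shape[0]))
    return Z @ L.T


def contaminate(
    X: np.ndarray, spec: ContaminationSpec, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Replace entries (or whole subjects) by Student-t(df) draws with prob `spec.prob`."""
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    if spec.prob == 0:
        return X.copy(), np.zeros(X.shape, dtype=bool)
    if spec.per_subject:
        rows = rng.random(X.shape[0]) < spec.prob
        mask = np.zeros(X.shape, dtype=bool)
        mask[rows] = True
    else:
        mask = rng.random(X.shape) < spec.prob
    Xc = X.copy()
    Xc[mask] = rng.standard_t(spec.df, size=int(mask.sum()))
    return Xc, mask


# ---------------------------------------------------------------------------
# survival and censoring draws


def draw_errors(n: int, error: ErrorModel, rng: np.random.Generator) -> np.ndarray:
    if error.family == "extreme_value_ph":
        # CDF 1 - exp(-e^u): the log of a unit exponential
        return np.log(rng.exponential(size=n))
    return rng.logistic(size=n)


def draw_survival(
    eta: np.ndarray, error: ErrorModel, seed: int | None = None
) -> np.ndarray:
    """T_i = H^{-1}(-eta_i + eps_i) under the chosen error family."""
    rng = np.random.default_rng(seed)
    eta = np.asarray(eta, dtype=float)
    eps = draw_errors(len(eta), error, rng)
    return transform_H_inv(-eta + eps)


def active_set_sampler(
    covariance: np.ndarray, effects: EffectSpec
) -> Callable[[int, np.random.Generator], np.ndarray]:
    """Sampler of the linear predictor eta using only the active covariates.

    Features outside the effect support contribute nothing to eta, so eta's
    distribution depends only on the support block of the covariance.  This
    makes the large Monte-Carlo draws used for censoring calibration cheap
    (tens of columns instead of thousands) while remaining exact.
    """
    sup = effects.support
    if len(sup) == 0:
        return lambda n, rng: np.zeros(n)
    sub_cov = np.asarray(covariance)[np.ix_(sup, sup)]
    L = np.linalg.cholesky(sub_cov)
    beta_sup = effects.beta[sup]
    links = None if effects.links is None else [effects.links[j] for j in sup]

    def sample(n: int, rng: np.random.Generator) -> np.ndarray:
        Xs = rng.standard_normal((n, len(sup))) @ L.T
        if links is None:
            return Xs @ beta_sup
        eta = np.zeros(n)
        for c, (lk, b) in enumerate(zip(links, beta_sup)):
            eta += apply_link(lk, b, Xs[:, c])
        return eta

    return sample


def calibrate_censoring(
    target_rate: float,
    time_sampler: Callable[[int, np.random.Generator], np.ndarray],
    tol: float = 0.005,
    n_mc: int = 200_000,
    seed: int | None = None,
    max_doublings: int = 60,
) -> CensoringSpec:
    """Find b so that C ~ U(0, b) censors about ``target_rate`` of subjects.

    With a frozen Monte-Carlo sample of survival times T, the censoring
    proportion P(T > C) = E[min(T, b)] / b is continuous and decreasing in
    b, so a bracketing bisection converges; ``time_sampler(n, rng)`` must
    return survival times.
    """
    if not 0 < target_rate < 1:
        raise ValueError("target_rate must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    T = np.asarray(time_sampler(n_mc, rng), dtype=float)
    if np.any(T <= 0):
        raise ValueError("time_sampler produced non-positive times")

    def rate(b: float) -> float:
        return float(np.mean(np.minimum(T, b)) / b)

    lo = float(np.quantile(T, 0.001)) / 2 or 1e-8
    hi = lo * 2
    for _ in range(max_doublings):
        if rate(hi) < target_rate:
            break
        lo, hi = hi, hi * 2
    else:
        raise RuntimeError(
            f"censoring rate {target_rate} unreachable; achievable range "
            f"({rate(hi):.4f}, {rate(lo):.4f}) over b in ({lo:.3g}, {hi:.3g})"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target_rate) <= tol:
            return CensoringSpec(a=0.0, b=float(mid), target_rate=target_rate)
        if r > target_rate:
            lo = mid
        else:
            hi = mid
    return CensoringSpec(a=0.0, b=float(mid), target_rate=target_rate)


# ---------------------------------------------------------------------------
# full scenario assembly


@dataclass(frozen=True)
class ScenarioConfig:
    """Composite description of one simulation design."""

    n: int = 500
    network: NetworkSpec = field(default_factory=NetworkSpec)
    effects: EffectSpec = field(default_factory=lambda: build_beta("sim1"))
    error: ErrorModel = field(default_factory=ErrorModel)
    censoring: CensoringSpec | None = None
    censoring_rate: float | None = 0.3
    contamination: ContaminationSpec | None = field(default_factory=ContaminationSpec)
    contaminate_before_eta: bool = False

    def __post_init__(self) -> None:
        if self.network.p != self.effects.p:
            raise ValueError("network p and effect-vector length disagree")
        if self.censoring is None and self.censoring_rate is not None:
            if not 0 < self.censoring_rate < 1:
                raise ValueError("censoring_rate must lie in (0, 1)")


def scenario_config(
    scenario: Literal["sim1", "sim2", "sim3"],
    n: int = 500,
    p: int = 2000,
    censoring_rate: float | None = 0.3,
    structure: Structure = "hub",
    error: Literal["extreme_value_ph", "logistic_po"] = "extreme_value_ph",
    contamination_prob: float = 0.1,
) -> ScenarioConfig:
    """Ready-made configs for the three study designs (see module docstring)."""
    if scenario in ("sim1", "sim2"):
        network = NetworkSpec(structure="ar1", p=p, rho=0.5)
        effects = build_beta("sim1", p) if scenario == "sim1" else build_links(p)
    elif scenario == "sim3":
        network = NetworkSpec(structure=structure, p=p)
        effects = build_beta("sim3", p)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    contamination = (
        ContaminationSpec(prob=contamination_prob) if contamination_prob > 0 else None
    )
    return ScenarioConfig(
        n=n,
        network=network,
        effects=effects,
        error=ErrorModel(error),
        censoring_rate=censoring_rate,
        contamination=contamination,
    )


def _resolve_censoring(
    config: ScenarioConfig, covariance: np.ndarray, seed: int
) -> CensoringSpec | None:
    if config.censoring is not None:
        return config.censoring
    if config.censoring_rate is None:
        return None
    sampler = active_set_sampler(covariance, config.effects)

    def time_sampler(n: int, rng: np.random.Generator) -> np.ndarray:
        eta = sampler(n, rng)
        eps = draw_errors(n, config.error, rng)
        return transform_H_inv(-eta + eps)

    return calibrate_censoring(config.censoring_rate, time_sampler, seed=seed)


def draw_outcomes(
    config: ScenarioConfig, n: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, CensoringSpec | None]:
    """(T, C, V, delta, censoring) without materialising the full covariate table.

    Uses the active-set sampler, so it is exact in distribution and suitable
    for very large Monte-Carlo validation cohorts.
    """
    ss = np.random.SeedSequence(seed)
    s_cal, s_draw = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    covariance, _ = generate_network_covariance(config.network, seed=s_cal)
    cens = _resolve_censoring(config, covariance, seed=s_cal)
    rng = np.random.default_rng(s_draw)
    eta = active_set_sampler(covariance, config.effects)(n, rng)
    eps = draw_errors(n, config.error, rng)
    T = transform_H_inv(-eta + eps)
    if cens is None:
        C = np.full(n, np.inf)
    else:
        C = rng.uniform(cens.a, cens.b, size=n)
    V = np.minimum(T, C)
    delta = (T <= C).astype(int)
    return T, C, V, delta, cens


def simulate(
    config: ScenarioConfig,
    seed: int | None = None,
    covariance: np.ndarray | None = None,
    adjacency: list[tuple[int, int]] | None = None,
) -> SimulatedCohort:
    """Generate one cohort: covariates, contamination, survival and censoring.

    Contamination models measurement corruption, so by default the latent
    survival times are computed from the clean covariates and only the
    covariate table handed to screeners is contaminated
    (``contaminate_before_eta`` flips this).  Passing a precomputed
    ``covariance`` skips the network build when replicating many cohorts.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5)]
    s_net, s_x, s_cont, s_surv, s_cens = seeds
    if covariance is None:
        covariance, adjacency = generate_network_covariance(config.network, seed=s_net)
    elif adjacency is None:
        adjacency = []
    cens = _resolve_censoring(config, covariance, seed=s_net)
    X_clean = draw_covariates(config.n, covariance, seed=s_x)
    if config.contamination is not None:
        X_obs, mask = contaminate(X_clean, config.contamination, seed=s_cont)
    else:
        X_obs, mask = X_clean.copy(), np.zeros(X_clean.shape, dtype=bool)
    eta_source = X_obs if config.contaminate_before_eta else X_clean
    eta = linear_predictor(eta_source, config.effects)
    T = draw_survival(eta, config.error, seed=s_surv)
    rng_c = np.random.default_rng(s_cens)
    if cens is None:
        C = np.full(config.n, np.inf)
    else:
        C = rng_c.uniform(cens.a, cens.b, size=config.n)
    V = np.minimum(T, C)
    delta = (T <= C).astype(int)
    return SimulatedCohort(
        X=X_obs,
        V=V,
        delta=delta,
        T_true=T,
        C_true=C,
        truth=config.effects.support,
        adjacency=list(adjacency or []),
        contaminated_mask=mask,
        censoring=cens,
    )
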