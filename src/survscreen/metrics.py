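"""Evaluation machinery for screening experiments.

Covers the minimum model size (MMS), overlap-coefficient and Jaccard set
similarities, Harrell's concordance for prediction, the Breslow Cox log
partial likelihood, the test-set deviance D = -2 (logL(beta-hat) - logL(0)),
and a replication benchmark driver that aggregates these over simulated
cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import cohorts as ch
from ._cox import breslow_loglik, null_loglik
from .data import ScreeningRanking, SurvivalData
from .network import AdjustmentSpec, rank_npn_mb
from .screening import MARGINAL_METHODS, concordance, rank_features

__all__ = [
    "mms",
    "overlap_coefficient",
    "jaccard_index",
    "method_similarity_matrix",
    "harrell_c",
    "cox_pll",
    "deviance",
    "MetricCurve",
    "BenchmarkConfig",
    "BenchmarkResult",
    "run_benchmark",
]

logger = logging.getLogger(__name__)

ALL_METHODS = MARGINAL_METHODS + ("MB", "NPN_MB")


def mms(ranking: ScreeningRanking, truth) -> int:
    """Minimum model size: smallest k whose top-k set covers every true feature."""
    truth = np.asarray(list(truth), dtype=int)
    if len(truth) == 0:
        raise ValueError("truth set must be non-empty")
    if truth.min() < 0 or truth.max() >= ranking.p:
        raise ValueError("truth contains feature ids outside the ranking")
    ranks = ranking.ranks()
    return int(ranks[truth].max())


def overlap_coefficient(selected, truth) -> float:
    """|A ∩ B| / min(|A|, |B|)."""
    A, B = set(selected), set(truth)
    if not A or not B:
        raise ValueError("overlap coefficient needs two non-empty sets")
    return len(A & B) / min(len(A), len(B))


def jaccard_index(A, B) -> float:
    """|A ∩ B| / |A ∪ B|."""
    A, B = set(A), set(B)
    if not A | B:
        raise ValueError("Jaccard index of two empty sets is undefined")
    return len(A & B) / len(A | B)


def method_similarity_matrix(
    rankings: Sequence[ScreeningRanking], model_size: int = 500
) -> np.ndarray:
    """Pairwise Jaccard similarity of the methods' top-``model_size`` sets."""
    if len(rankings) < 2:
        raise ValueError("need at least two rankings")
    p = rankings[0].p
    if any(r.p != p for r in rankings):
        raise ValueError("rankings must share the feature universe")
    if model_size > p:
        warnings.warn(f"model_size {model_size} > p = {p}; clipped", stacklevel=2)
        model_size = p
    tops = [set(r.top(model_size).tolist()) for r in rankings]
    m = len(tops)
    S = np.eye(m)
    for i in range(m):
        for k in range(i + 1, m):
            S[i, k] = S[k, i] = jaccard_index(tops[i], tops[k])
    return S


def harrell_c(score, V, delta) -> float:
    """Harrell's concordance of a risk score against censored survival."""
    return concordance(score, V, delta)


def cox_pll(beta, data: SurvivalData) -> float:
    """Breslow Cox log partial likelihood at fixed coefficients (no fitting)."""
    beta = np.asarray(beta, dtype=float)
    if len(beta) != data.p:
        raise ValueError("beta length must equal the number of features")
    if np.all(beta == 0):
        return null_loglik(data.V, data.delta)
    return breslow_loglik(data.X @ beta, data.V, data.delta)


def deviance(beta_hat, test: SurvivalData) -> float:
    """Test-set deviance D = -2 (logL(beta-hat) - logL(0)); 0 for the null model.

    Negative values mean the fitted model beats the null on the test set;
    the caller is responsible for estimating beta-hat on disjoint training
    data.
    """
    return -2.0 * (cox_pll(beta_hat, test) - null_loglik(test.V, test.delta))


# ---------------------------------------------------------------------------
# replication benchmark


@dataclass
class MetricCurve:
    """A metric evaluated on a grid of model sizes, aggregated over replications."""

    model_sizes: np.ndarray
    values: np.ndarray
    n_replications: int
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        self.model_sizes = np.asarray(self.model_sizes, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.model_sizes) != len(self.values):
            raise ValueError("grid and values lengths disagree")


@dataclass
class BenchmarkConfig:
    """Replication study over one simulation design.

    ``replications`` defaults to the desk-scale 20; the full-scale studies
    use 200.  ``compute_cindex`` adds the held-out concordance curve (a Cox
    refit per grid size per replication, the slow part).
    """

    scenario: ch.ScenarioConfig = field(default_factory=lambda: ch.scenario_config("sim1"))
    methods: tuple[str, ...] = ("SIS", "IPCW_TAU")
    replications: int = 20
    model_sizes: tuple[int, ...] = (10, 20, 50, 100, 200)
    similarity_size: int = 500
    compute_cindex: bool = False
    cindex_penalizer: float = 1e-4
    adjustment: AdjustmentSpec = field(default_factory=AdjustmentSpec)
    mb_lambda: float | None = None
    mb_pre_cap: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        bad = [m for m in self.methods if m not in ALL_METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; choose from {ALL_METHODS}")


@dataclass
class BenchmarkResult:
    methods: tuple[str, ...]
    mms_samples: dict[str, np.ndarray]
    overlap_curves: dict[str, MetricCurve]
    cindex_curves: dict[str, MetricCurve] | None
    similarity: np.ndarray
    n_failures: int
    config: BenchmarkConfig

    def median_mms(self) -> dict[str, float]:
        return {m: float(np.median(v)) for m, v in self.mms_samples.items()}


def _rank_by_method(
    data: SurvivalData, method: str, config: BenchmarkConfig, tau_cache: dict
) -> ScreeningRanking:
    if method in ("MB", "NPN_MB"):
        return rank_npn_mb(
            data,
            spec=config.adjustment,
            lam=config.mb_lambda,
            transform=(method == "NPN_MB"),
            pre_cap=config.mb_pre_cap,
            tau_abs=tau_cache.get("tau_abs"),
        )
    ranking = rank_features(data, method)
    if method == "IPCW_TAU":
        tau_cache["tau_abs"] = ranking.utilities
    return ranking


def _heldout_cindex(
    cohort: ch.SimulatedCohort,
    ranking: ScreeningRanking,
    sizes: np.ndarray,
    rng: np.random.Generator,
    penalizer: float,
) -> np.ndarray:
    """Ridge-stabilised Cox refit on the top-k train features; C on held-out half."""
    import pandas as pd
    from lifelines import CoxPHFitter

    n = cohort.n
    perm = rng.permutation(n)
    tr, te = perm[: n // 2], perm[n // 2 :]
    out = np.full(len(sizes), np.nan)
    for s_idx, k in enumerate(sizes):
        feats = ranking.top(int(k))
        df = pd.DataFrame(cohort.X[np.ix_(tr, feats)])
        df.columns = [str(c) for c in df.columns]
        df["T"] = cohort.V[tr]
        df["E"] = cohort.delta[tr]
        try:
            cph = CoxPHFitter(penalizer=max(penalizer, 1e-6 * len(feats)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="T", event_col="E")
            score = cohort.X[np.ix_(te, feats)] @ cph.params_.to_numpy()
            out[s_idx] = harrell_c(score, cohort.V[te], cohort.delta[te])
        except Exception as exc:  # noqa: BLE001 - per-size failures are recorded, not fatal
            logger.warning("c-index refit failed at size %d: %s", k, exc)
    return out


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Replicate: simulate, screen with every method, record MMS and curves.

    The network covariance is built once and shared across replications;
    each replication draws an independent cohort from a child seed of the
    master seed.  Per-replication failures are logged and skipped; more
    than 10% failures aborts.
    """
    from dataclasses import replace

    cfg = config
    covariance, adjacency = ch.generate_network_covariance(
        cfg.scenario.network, seed=cfg.seed
    )
    # calibrate censoring once; replications then share the resolved (a, b)
    scenario = cfg.scenario
    if scenario.censoring is None and scenario.censoring_rate is not None:
        cens = ch._resolve_censoring(scenario, covariance, seed=cfg.seed)
        scenario = replace(scenario, censoring=cens)
    sizes = np.asarray(cfg.model_sizes, dtype=int)
    sizes = sizes[sizes <= cfg.scenario.network.p]
    mms_samples: dict[str, list] = {m: [] for m in cfg.methods}
    overlap_acc = {m: np.zeros(len(sizes)) for m in cfg.methods}
    cindex_acc = {m: np.zeros(len(sizes)) for m in cfg.methods}
    cindex_cnt = {m: np.zeros(len(sizes)) for m in cfg.methods}
    sim_acc = np.zeros((len(cfg.methods), len(cfg.methods)))
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(cfg.replications)]
    failures = 0
    completed = 0
    for rep, child in enumerate(child_seeds):
        try:
            cohort = ch.simulate(
                scenario, seed=child, covariance=covariance, adjacency=adjacency
            )
            data = cohort.to_survival_data()
            truth = set(cohort.truth.tolist())
            tau_cache: dict = {}
            rankings = []
            rng_split = np.random.default_rng(child + 1)
            for m in cfg.methods:
                ranking = _rank_by_method(data, m, cfg, tau_cache)
                rankings.append(ranking)
                mms_samples[m].append(mms(ranking, truth))
                for s_idx, k in enumerate(sizes):
                    overlap_acc[m][s_idx] += overlap_coefficient(
                        ranking.top(int(k)).tolist(), truth
                    )
                if cfg.compute_cindex:
                    cs = _heldout_cindex(cohort, ranking, sizes, rng_split, cfg.cindex_penalizer)
                    ok = ~np.isnan(cs)
                    cindex_acc[m][ok] += cs[ok]
                    cindex_cnt[m][ok] += 1
            if len(cfg.methods) >= 2:
                sim_acc += method_similarity_matrix(rankings, cfg.similarity_size)
            completed += 1
        except Exception as exc:  # noqa: BLE001 - replication-level robustness
            failures += 1
            logger.warning("replication %d failed: %s", rep, exc)
            if failures > max(1, 0.1 * cfg.replications):
                raise RuntimeError(
                    f"{failures} of {rep + 1} replications failed; aborting"
                ) from exc
    if completed == 0:
        raise RuntimeError("all replications failed")
    overlap_curves = {
        m: MetricCurve(sizes, overlap_acc[m] / completed, completed) for m in cfg.methods
    }
    cindex_curves = None
    if cfg.compute_cindex:
        cindex_curves = {
            m: MetricCurve(
                sizes,
                np.where(cindex_cnt[m] > 0, cindex_acc[m] / np.maximum(cindex_cnt[m], 1), np.nan),
                completed,
            )
            for m in cfg.methods
        }
    return BenchmarkResult(
        methods=cfg.methods,
        mms_samples={m: np.asarray(v) for m, v in mms_samples.items()},
        overlap_curves=overlap_curves,
        cindex_curves=cindex_curves,
        similarity=sim_acc / completed if len(cfg.methods) >= 2 else np.eye(1),
        n_failures=failures,
        config=cfg,
    )
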