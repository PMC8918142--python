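"""Real-data analysis protocol for expression + survival tables.

The protocol mirrors common practice for TCGA-style RNA-Seq survival
analyses: (1) load a samples x features expression table and a clinical
table (sample id, observed time, event status); (2) prefilter to the k
features with the smallest marginal-Cox Wald p-values; (3) rank the
remaining features with a screening method and hard-threshold to the top d;
(4) fit a sparse Cox model on the retained features via a pluggable fitter
(a ridge-penalized Cox fit ships as the default; an adapter hook accepts an
external sparse solver such as an MCP-penalized fit); (5) report test-set
deviance, Harrell's c-index, and the number of selected features (NOSF)
over repeated random train/test splits, summarised by medians.

By default the prefilter runs inside each training fold so no test-set
information reaches feature selection; ``whole_data_prefilter=True`` prefilters
once on the whole data instead, which matches the common published variant
at the cost of a mild selection leak.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._cox import univariate_cox
from .data import SurvivalData
from .metrics import deviance, harrell_c
from .network import AdjustmentSpec, rank_npn_mb
from .screening import rank_features

__all__ = [
    "PipelineConfig",
    "SplitReport",
    "load_dataset",
    "prefilter_univariate_cox",
    "make_fitter",
    "ridge_cox_fitter",
    "screen_threshold_fit",
    "evaluate_splits",
]

logger = logging.getLogger(__name__)

#: coefficients below this magnitude count as zero in NOSF
NOSF_TOL = 1e-8

# a fitter maps (X, V, delta) for the retained features to a coefficient vector
Fitter = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


@dataclass
class PipelineConfig:
    prefilter_k: int = 2000
    top_d: int | Sequence[int] = field(default_factory=lambda: tuple(range(10, 301, 10)))
    n_splits: int = 5
    train_fraction: float = 0.8
    method: str = "IPCW_TAU"
    fitter: str | Fitter = "ridge"
    whole_data_prefilter: bool = False
    adjustment: AdjustmentSpec = field(default_factory=AdjustmentSpec)
    mb_lambda: float | None = None
    mb_pre_cap: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if self.prefilter_k < 1:
            raise ValueError("prefilter_k must be >= 1")


@dataclass
class SplitReport:
    """Per-split prediction metrics and their medians."""

    deviance: list[float]
    cindex: list[float]
    nosf: list[int]
    top_d_selected: int
    n_failed_splits: int
    grid_cindex: dict[int, float] | None = None

    @property
    def median_deviance(self) -> float:
        return float(np.median(self.deviance))

    @property
    def median_cindex(self) -> float:
        return float(np.median(self.cindex))

    @property
    def median_nosf(self) -> float:
        return float(np.median(self.nosf))


# ---------------------------------------------------------------------------
# loading


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def load_dataset(
    expression_path,
    clinical_path,
    time_col: str = "time",
    status_col: str = "status",
) -> SurvivalData:
    """Inner-join an expression table (samples x features) with clinical outcomes.

    Rows with missing time or status are dropped with a logged count;
    zero-variance features are removed with a logged list; times must be
    positive after cleaning.
    """
    expr = _read_table(expression_path)
    clin = _read_table(clinical_path)
    for col in (time_col, status_col):
        if col not in clin.columns:
            raise ValueError(f"clinical table lacks required column {col!r}")
    common = expr.index.intersection(clin.index)
    if len(common) == 0:
        raise ValueError("no overlapping sample ids between expression and clinical tables")
    expr, clin = expr.loc[common], clin.loc[common]
    ok = clin[time_col].notna() & clin[status_col].notna()
    if (~ok).any():
        logger.info("dropping %d samples with missing time/status", int((~ok).sum()))
        expr, clin = expr.loc[ok], clin.loc[ok]
    try:
        X = expr.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = expr.columns[expr.apply(lambda c: pd.to_numeric(c, errors="coerce").isna().any())]
        raise ValueError(f"non-numeric expression values in columns: {list(bad)[:5]}") from exc
    const = np.ptp(X, axis=0) == 0
    if const.any():
        logger.info("removing %d zero-variance features: %s",
                    int(const.sum()), list(expr.columns[const])[:10])
        expr = expr.loc[:, ~const]
        X = X[:, ~const]
    return SurvivalData(
        X,
        clin[time_col].to_numpy(dtype=float),
        clin[status_col].to_numpy(dtype=int),
        feature_names=list(expr.columns),
    )


# ---------------------------------------------------------------------------
# prefilter / screen / fit


def prefilter_univariate_cox(data: SurvivalData, k: int) -> SurvivalData:
    """Keep the k features with the smallest marginal-Cox Wald p-values.

    Ties break by ascending feature id; a failed marginal fit gets p = 1
    and is logged.  ``k >= p`` returns the data unchanged.
    """
    from scipy import stats

    if k >= data.p:
        return data
    pvals = np.ones(data.p)
    for j in range(data.p):
        try:
            beta, _, se = univariate_cox(data.X[:, j], data.V, data.delta)
            if np.isfinite(se) and se > 0:
                pvals[j] = 2.0 * stats.norm.sf(abs(beta / se))
        except Exception as exc:  # noqa: BLE001 - robust prefilter contract
            logger.warning("marginal Cox fit failed for feature %d: %s", j, exc)
    keep = np.lexsort((np.arange(data.p), pvals))[:k]
    return data.subset_features(np.sort(keep))


def ridge_cox_fitter(penalizer: float = 0.1) -> Fitter:
    """Ridge-penalized Cox fit via lifelines; the shipped default fitter."""
    from lifelines import CoxPHFitter

    def fit(X: np.ndarray, V: np.ndarray, delta: np.ndarray) -> np.ndarray:
        df = pd.DataFrame(X, columns=[str(j) for j in range(X.shape[1])])
        df["T"], df["E"] = V, delta
        cph = CoxPHFitter(penalizer=penalizer, l1_ratio=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
        return cph.params_.to_numpy()

    return fit


def make_fitter(tag: str | Fitter, **kwargs) -> Fitter:
    """Resolve a fitter tag; callables pass through (the external-solver hook)."""
    if callable(tag):
        return tag
    if tag == "ridge":
        return ridge_cox_fitter(**kwargs)
    if tag == "external":
        raise NotImplementedError(
            "no external sparse-Cox solver is registered; pass a callable "
            "fitter (X, V, delta) -> coefficients instead"
        )
    raise ValueError(f"unknown fitter {tag!r}")


def _rank(data: SurvivalData, config: PipelineConfig):
    m = config.method.upper().replace("-", "_")
    if m in ("MB", "NPN_MB"):
        return rank_npn_mb(
            data,
            spec=config.adjustment,
            lam=config.mb_lambda,
            transform=(m == "NPN_MB"),
            pre_cap=config.mb_pre_cap,
        )
    return rank_features(data, m)


def screen_threshold_fit(
    train: SurvivalData, config: PipelineConfig, top_d: int, fitter: Fitter
) -> np.ndarray:
    """Rank on the training data, hard-threshold to top_d, delegate the fit.

    Returns the coefficient vector embedded back into the training feature
    space (zeros outside the retained set).
    """
    ranking = _rank(train, config)
    feats = ranking.top(top_d)
    coefs = fitter(train.X[:, feats], train.V, train.delta)
    beta = np.zeros(train.p)
    beta[feats] = coefs
    return beta


def _split_indices(
    n: int, train_fraction: float, n_splits: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    ss = np.random.SeedSequence(seed)
    out = []
    n_train = int(np.floor(n * train_fraction))
    for child in ss.spawn(n_splits):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        out.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return out


def evaluate_splits(data: SurvivalData, config: PipelineConfig) -> SplitReport:
    """Run the full protocol over repeated random train/test splits.

    When ``top_d`` is a grid, each grid value is evaluated on every split
    and the value maximising the median held-out c-index wins; the reported
    per-split metrics are those of the winning model size.
    """
    fitter = make_fitter(config.fitter)
    splits = _split_indices(data.n, config.train_fraction, config.n_splits, config.seed)
    grid = [config.top_d] if np.isscalar(config.top_d) else list(config.top_d)
    grid = [int(d) for d in grid]

    whole_pref = (
        prefilter_univariate_cox(data, config.prefilter_k) if config.whole_data_prefilter else None
    )

    # cache per-split rankings: screening does not depend on top_d
    per_split: list[dict] = []
    for tr_idx, te_idx in splits:
        try:
            if config.whole_data_prefilter:
                train = whole_pref.subset_subjects(tr_idx)
                test = whole_pref.subset_subjects(te_idx)
            else:
                train_full = data.subset_subjects(tr_idx)
                train = prefilter_univariate_cox(train_full, config.prefilter_k)
                name_to_idx = {f: i for i, f in enumerate(data.feature_names)}
                keep = [name_to_idx[f] for f in train.feature_names]
                test = data.subset_subjects(te_idx).subset_features(np.asarray(keep))
            ranking = _rank(train, config)
            per_split.append({"train": train, "test": test, "ranking": ranking})
        except Exception as exc:  # noqa: BLE001 - per-split robustness
            logger.warning("split failed during screening: %s", exc)
            per_split.append(None)
    if all(s is None for s in per_split):
        raise RuntimeError("all splits failed")

    def metrics_at(d: int) -> tuple[list[float], list[float], list[int], int]:
        devs, cis, nosfs, failed = [], [], [], 0
        for s in per_split:
            if s is None:
                failed += 1
                continue
            train, test, ranking = s["train"], s["test"], s["ranking"]
            try:
                feats = ranking.top(min(d, train.p))
                coefs = fitter(train.X[:, feats], train.V, train.delta)
                beta = np.zeros(train.p)
                beta[feats] = coefs
                score = test.X @ beta
                devs.append(deviance(beta, test))
                cis.append(harrell_c(score, test.V, test.delta))
                nosfs.append(int(np.sum(np.abs(coefs) > NOSF_TOL)))
            except Exception as exc:  # noqa: BLE001
                logger.warning("split failed during fitting at d=%d: %s", d, exc)
                failed += 1
        return devs, cis, nosfs, failed

    grid_cindex: dict[int, float] = {}
    best_d, best_ci = grid[0], -np.inf
    cache: dict[int, tuple] = {}
    for d in grid:
        devs, cis, nosfs, failed = metrics_at(d)
        cache[d] = (devs, cis, nosfs, failed)
        med = float(np.median(cis)) if cis else -np.inf
        grid_cindex[d] = med
        if med > best_ci:
            best_d, best_ci = d, med
    devs, cis, nosfs, failed = cache[best_d]
    if not devs:
        raise RuntimeError("all splits failed")
    return SplitReport(
        deviance=devs,
        cindex=cis,
        nosf=nosfs,
        top_d_selected=best_d,
        n_failed_splits=failed,
        grid_cindex=grid_cindex if len(grid) > 1 else None,
    )
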