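# survscreen

Feature screening for right-censored survival outcomes when the number of
covariates vastly exceeds the sample size — the situation of TCGA-style
RNA-Seq studies where ~20,000 gene expression values are measured on a few
hundred patients with (often heavily censored) survival follow-up.

Screening ranks every feature by a *marginal utility* — a per-feature
association score with the survival outcome — and retains only the
top-ranked candidates for downstream penalized model fitting.  `survscreen`
implements eight utilities spanning the main families, a transformation-model
cohort simulator with gene-network covariate structures, and the evaluation
machinery to compare them.

## Methods

With observed time `V = min(T, C)` and event indicator `δ = 1{T ≤ C}`:

| Tag | Utility |
|-----|---------|
| `PL` | maximized marginal Cox partial-likelihood gain ℓ(β̂) − ℓ(0) |
| `SIS` | \|Pearson corr(x, log V)\| (ad hoc; ignores censoring) |
| `FAST` | feature aberration at event times: average deviation of a standardized covariate from its at-risk mean |
| `CINDEX` | \|Harrell's C − ½\| of the covariate as a risk score |
| `IPCW_TAU` | Kendall's tau over pairs, weighted 1/Ĝ(Ṽ−)² by the Kaplan–Meier estimate Ĝ of the censoring survivor function |
| `RCDCS` | distance correlation of the covariate ECDF with the Kaplan–Meier CDF of T |
| `CRCDCS` | composite of IPCW-weighted distance correlations of survival-status indicators at KM quantiles |
| `NPN_MB` / `MB` | IPCW-tau utilities smoothed along an estimated gene–gene dependency graph |

The network-adjusted screener estimates a sparse conditional-independence
graph by Meinshausen–Bühlmann neighborhood selection (nodewise lasso at
penalty √(log p / n)) — on nonparanormal-transformed covariates for
`NPN_MB`, raw covariates for `MB` — and propagates the absolute tau
utilities one step along the graph's row-stochastic random-walk matrix:
u = (1 − α)·|τ̂| + α·W u (α = 0.5).  Correlated neighbors of strong
features are pulled up; isolated noise features are not.

The simulator draws survival times from the linear transformation model
H(T) = −x′β + ε with H(t) = log(0.5(e²ᵗ − 1)); an extreme-value ε gives a
proportional-hazards model, a logistic ε proportional odds.  Covariates are
Gaussian with AR(1), band, hub, cluster or scale-free network correlation;
entries are contaminated by t(2) outliers with probability 0.1; uniform
censoring U(0, b) is calibrated by Monte-Carlo bisection to a 30/50/70%
target rate.

## Worked example

Screen a simulated cohort (n = 400 subjects, p = 500 features, 30%
censoring, 14 true predictors, AR(1) correlation, 10% outlier
contamination) and compare screening accuracy over 10 replications:

```python
import survscreen as sv

cfg = sv.BenchmarkConfig(
    scenario=sv.scenario_config("sim1", n=400, p=500, censoring_rate=0.3),
    methods=("SIS", "IPCW_TAU", "NPN_MB"),
    replications=10,
    model_sizes=(20, 50, 100),
    seed=7,
)
res = sv.run_benchmark(cfg)
print("median MMS:", res.median_mms())
for m, c in res.overlap_curves.items():
    print(f"overlap {m}:", dict(zip(c.model_sizes.tolist(), c.values.round(2).tolist())))
```

prints

```
median MMS: {'SIS': 431.0, 'IPCW_TAU': 352.0, 'NPN_MB': 94.0}
overlap SIS: {20: 0.61, 50: 0.72, 100: 0.78}
overlap IPCW_TAU: {20: 0.71, 50: 0.76, 100: 0.84}
overlap NPN_MB: {20: 0.72, 50: 0.87, 100: 0.96}
```

The minimum model size (MMS) is the smallest number of top-ranked features
needed to cover all 14 true predictors (lower is better; 14 is the floor).
The overlap coefficient |A ∩ truth| / min(|A|, |truth|) measures how much
of the truth the top-k set captures.  Here the network-adjusted screener
needs a median of 94 features to cover the truth where the plain IPCW-tau
ranking needs 352 — the dependency graph rescues weak-but-connected true
features.

The same methods run from the shell:

```bash
survscreen simulate --scenario sim1 --n 400 --p 500 --seed 1 --out-prefix cohort
survscreen screen --method NPN_MB --expression cohort_covariates.tsv \
    --clinical cohort_outcomes.tsv --out ranking.tsv
survscreen benchmark --scenario sim1 --methods IPCW_TAU,NPN_MB --out-dir bench/
survscreen predict --expression expr.tsv --clinical clin.tsv \
    --method IPCW_TAU --top-d-grid 10:300:10 --out-prefix results
```

`predict` runs the real-data protocol: marginal-Cox prefilter to the top
2,000 features, screening, hard-thresholding to the top d (grid-searched by
median held-out c-index), a sparse Cox fit (ridge-penalized by default,
pluggable), and median test-set deviance / c-index / number of selected
features over repeated random ~4:1 train/test splits.

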