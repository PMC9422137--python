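"""Conditional logistic (matched 1:k) selection models, AIC comparison, RSS.

The estimator maximizes the stratum-wise conditional likelihood

    l(beta) = sum_s [ beta' x_used(s) - log sum_{j in s} exp(beta' x_j) ]

directly by Newton iterations with analytic gradient and Hessian. With one
used candidate per stratum this is identical to the Cox partial likelihood
(Breslow ties), which is how such models are usually fit; the direct softmax
form is simpler and exactly testable. All 2^5 subsets of the covariate
blocks {FENCE, RNF, R1F, R2F, LANDCOVER} are ranked by AIC; the selected
model is refit on Gelman-standardized covariates (center by the mean, scale
by twice the SD) so coefficients are comparable across covariates; effects
are reported as log relative selection strength, log-RSS = beta'(x1 - x2).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import LANDCOVER_CATEGORIES, LANDCOVER_REFERENCE
from .features import ConfigClass

logger = logging.getLogger(__name__)

BLOCKS = ("FENCE", "RNF", "R1F", "R2F", "LANDCOVER")
LANDCOVER_LEVELS = tuple(c for c in LANDCOVER_CATEGORIES if c != LANDCOVER_REFERENCE)

# Separation guard: |beta| beyond any plausible selection strength on a
# standardized or count scale. Must sit below ~20: past that the conditional
# likelihood's gradient underflows and the fit "converges" on a divergent path.
MAX_ABS_BETA = 15.0
GRAD_TOL = 1e-8
REL_LL_TOL = 1e-12
MAX_ITER = 100


@dataclass(frozen=True)
class ModelSpec:
    """A subset of covariate blocks at one analysis scale."""

    blocks: frozenset[str]
    scale: str  # "crossing" | "proximity"

    def __post_init__(self) -> None:
        unknown = self.blocks - set(BLOCKS)
        if unknown:
            raise ValueError(f"unknown blocks: {sorted(unknown)}")
        if self.scale not in ("crossing", "proximity"):
            raise ValueError(f"unknown scale: {self.scale}")

    @property
    def covariates(self) -> list[str]:
        prefix = "n_cross_" if self.scale == "crossing" else "dist_"
        cols = [f"{prefix}{cc.value}" for cc in ConfigClass if cc.value in self.blocks]
        if "LANDCOVER" in self.blocks:
            cols += [f"lc_{lvl}" for lvl in LANDCOVER_LEVELS]
        return cols

    @property
    def label(self) -> str:
        if not self.blocks:
            return "null"
        return "+".join(b for b in BLOCKS if b in self.blocks)


def all_model_specs(scale: str) -> list[ModelSpec]:
    """All 2^5 block subsets (the empty set is the null model)."""
    specs = []
    for r in range(len(BLOCKS) + 1):
        for combo in itertools.combinations(BLOCKS, r):
            specs.append(ModelSpec(frozenset(combo), scale))
    return specs


def expand_landcover(table: pd.DataFrame) -> pd.DataFrame:
    """Add lc_* indicator columns (reference category ANNUAL_CROP omitted)."""
    out = table.copy()
    for lvl in LANDCOVER_LEVELS:
        out[f"lc_{lvl}"] = (out["landcover"] == lvl).astype(float)
    return out


@dataclass
class PreparedStrata:
    """Sorted candidate arrays ready for the fitter, shared across model specs."""

    columns: list[str]
    X_full: np.ndarray  # (n_candidates, n_columns), stratum-contiguous
    case: np.ndarray  # bool
    starts: np.ndarray  # first row of each stratum
    sizes: np.ndarray  # candidates per stratum
    groups: np.ndarray | None = None  # cluster label per stratum (e.g. animal)

    @property
    def n_strata(self) -> int:
        return len(self.starts)

    def design(self, covariates: list[str]) -> np.ndarray:
        idx = [self.columns.index(c) for c in covariates]
        return self.X_full[:, idx] if idx else np.empty((len(self.case), 0))


def prepare_strata(
    table: pd.DataFrame, columns: list[str], group_col: str | None = None
) -> PreparedStrata:
    """Sort by stratum and drop strata that are incomplete (not exactly one
    used candidate, or any missing covariate value)."""
    df = table.sort_values(["stratum_id", "case"], kind="mergesort")
    codes, _ = pd.factorize(df["stratum_id"], sort=False)
    X = df[columns].to_numpy(dtype=float) if columns else np.empty((len(df), 0))
    case = df["case"].to_numpy(dtype=int)
    starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
    n = len(codes)
    sizes = np.diff(np.r_[starts, n])
    case_per = np.add.reduceat(case, starts)
    bad_row = np.isnan(X).any(axis=1) if X.size else np.zeros(n, dtype=bool)
    bad_per = np.add.reduceat(bad_row.astype(int), starts) > 0
    ok = (case_per == 1) & ~bad_per
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d incomplete strata", n_dropped)
    groups = None
    if group_col is not None:
        groups = df[group_col].to_numpy()[starts][ok]
    keep = np.repeat(ok, sizes)
    X, case = X[keep], case[keep].astype(bool)
    sizes = sizes[ok]
    starts = np.r_[0, np.cumsum(sizes)[:-1]]
    return PreparedStrata(list(columns), X, case, starts, sizes, groups)


def _stratum_lse(eta: np.ndarray, starts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    m = np.maximum.reduceat(eta, starts)
    return m + np.log(np.add.reduceat(np.exp(eta - np.repeat(m, sizes)), starts))


def conditional_loglik(
    beta: np.ndarray, X: np.ndarray, starts: np.ndarray, sizes: np.ndarray, case: np.ndarray
) -> float:
    """Matched conditional log-likelihood (softmax per stratum)."""
    eta = X @ beta if X.shape[1] else np.zeros(len(case))
    lse = _stratum_lse(eta, starts, sizes)
    return float(eta[case].sum() - lse.sum())


def _loglik_grad_hess(beta, X, starts, sizes, case):
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    lse = _stratum_lse(eta, starts, sizes)
    ll = float(eta[case].sum() - lse.sum())
    if p == 0:
        return ll, np.zeros(0), np.zeros((0, 0))
    w = np.exp(eta - np.repeat(lse, sizes))  # softmax weights within stratum
    mu = np.add.reduceat(w[:, None] * X, starts, axis=0)  # per-stratum E[x]
    grad = X[case].sum(axis=0) - mu.sum(axis=0)
    hess = -(X.T @ (w[:, None] * X) - mu.T @ mu)
    return ll, grad, hess


@dataclass
class FitResult:
    spec: ModelSpec
    covariates: list[str]
    beta: pd.Series
    se: pd.Series
    loglik: float
    aic: float
    n_strata: int
    converged: bool
    separation: bool = False
    vcov: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.covariates)


def fit(
    spec: ModelSpec, table: pd.DataFrame, prepared: PreparedStrata | None = None
) -> FitResult:
    """Newton fit of one model spec on a covariate table.

    Starts at beta = 0 (the equal-probability model); step-halving keeps the
    likelihood non-decreasing; separation is flagged when any |beta| runs
    past MAX_ABS_BETA.
    """
    covs = spec.covariates
    if prepared is None:
        prepared = prepare_strata(table, covs)
    X = prepared.design(covs)
    starts, sizes, case = prepared.starts, prepared.sizes, prepared.case
    n_strata = prepared.n_strata
    if n_strata == 0:
        raise ValueError("no complete strata to fit")
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, X, starts, sizes, case)
    converged = p == 0
    separation = False
    for _ in range(MAX_ITER if p else 0):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            logger.warning("singular information matrix for %s", spec.label)
            break
        new_beta, new_ll = beta + step, -np.inf
        for _half in range(30):
            new_ll = conditional_loglik(new_beta, X, starts, sizes, case)
            if new_ll >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        rel_change = abs(new_ll - ll) / max(1.0, abs(ll))
        beta = new_beta
        ll, grad, hess = _loglik_grad_hess(beta, X, starts, sizes, case)
        if np.max(np.abs(beta)) > MAX_ABS_BETA:
            separation = True
            logger.warning("separation suspected for %s: max|beta| > %g", spec.label, MAX_ABS_BETA)
            break
        if np.max(np.abs(grad)) < GRAD_TOL or rel_change < REL_LL_TOL:
            converged = True
            break
    if p and np.max(np.abs(beta)) > MAX_ABS_BETA:
        separation = True
    if p:
        try:
            vcov = np.linalg.inv(-hess)
            se = np.sqrt(np.clip(np.diag(vcov), 0, None))
        except np.linalg.LinAlgError:
            vcov = np.full((p, p), np.nan)
            se = np.full(p, np.nan)
    else:
        vcov = np.zeros((0, 0))
        se = np.zeros(0)
    converged = converged and not separation
    aic = 2 * p - 2 * ll
    return FitResult(
        spec=spec,
        covariates=covs,
        beta=pd.Series(beta, index=covs),
        se=pd.Series(se, index=covs),
        loglik=ll,
        aic=aic,
        n_strata=n_strata,
        converged=converged,
        separation=separation,
        vcov=vcov,
    )


def cluster_robust_se(
    fit_result: FitResult, table: pd.DataFrame, cluster_col: str = "animal_id"
) -> pd.Series:
    """Sandwich standard errors clustered on ``cluster_col`` (typically the
    animal).

    Strata from one individual share a trajectory and are serially dependent,
    so model-based SEs understate uncertainty; the sandwich A^-1 B A^-1 with
    scores summed within clusters (and a G/(G-1) small-sample factor) accounts
    for it.
    """
    covs = fit_result.covariates
    prepared = prepare_strata(table, covs, group_col=cluster_col)
    X = prepared.design(covs)
    beta = fit_result.beta.to_numpy()
    eta = X @ beta
    lse = _stratum_lse(eta, prepared.starts, prepared.sizes)
    w = np.exp(eta - np.repeat(lse, prepared.sizes))
    mu = np.add.reduceat(w[:, None] * X, prepared.starts, axis=0)
    scores = X[prepared.case] - mu  # per-stratum score at beta-hat
    labels, inv = np.unique(prepared.groups, return_inverse=True)
    G = len(labels)
    g = np.zeros((G, len(covs)))
    np.add.at(g, inv, scores)
    B = g.T @ g * (G / max(G - 1, 1))
    A_inv = fit_result.vcov  # inverse observed information
    vcov_r = A_inv @ B @ A_inv
    return pd.Series(np.sqrt(np.clip(np.diag(vcov_r), 0, None)), index=covs)


@dataclass
class ModelComparison:
    """All-subsets AIC ranking with Akaike weights."""

    table: pd.DataFrame  # columns: model, k, loglik, aic, delta_aic, weight
    fits: dict[str, FitResult] = field(default_factory=dict)
    delta_aic_cutoff: float = 2.0

    @property
    def top(self) -> FitResult:
        return self.fits[self.table.iloc[0]["model"]]

    @property
    def competing(self) -> pd.DataFrame:
        return self.table[self.table["delta_aic"] < self.delta_aic_cutoff]


def compare_models(
    table: pd.DataFrame, scale: str, delta_aic_cutoff: float = 2.0
) -> ModelComparison:
    """Fit all 32 block subsets and rank by AIC."""
    specs = all_model_specs(scale)
    all_cols = sorted({c for s in specs for c in s.covariates})
    prepared = prepare_strata(table, all_cols)
    fits: dict[str, FitResult] = {}
    rows = []
    for spec in specs:
        res = fit(spec, table, prepared=prepared)
        fits[spec.label] = res
        if not res.converged:
            logger.warning("model %s did not converge; excluded from weights", spec.label)
        rows.append((spec.label, res.k, res.loglik, res.aic, res.converged))
    df = pd.DataFrame(rows, columns=["model", "k", "loglik", "aic", "converged"])
    ok = df[df["converged"]].sort_values(["aic", "k", "model"], kind="mergesort").reset_index(drop=True)
    ok["delta_aic"] = ok["aic"] - ok["aic"].iloc[0]
    rel = np.exp(-ok["delta_aic"] / 2.0)
    ok["weight"] = rel / rel.sum()
    return ModelComparison(table=ok, fits=fits, delta_aic_cutoff=delta_aic_cutoff)


@dataclass
class StandardizationRecipe:
    """Gelman standardization: center at the mean, scale by 2 SD.

    Puts continuous covariates on a scale comparable to +/-0.5-coded binary
    indicators; indicator covariates are left untouched.
    """

    center: dict[str, float]
    scale: dict[str, float]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, c in self.center.items():
            out[col] = (out[col] - c) / self.scale[col]
        return out

    def inverse(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, c in self.center.items():
            out[col] = out[col] * self.scale[col] + c
        return out


def standardize_and_refit(
    spec: ModelSpec, table: pd.DataFrame
) -> tuple[StandardizationRecipe, FitResult]:
    """Refit a selected model on Gelman-standardized continuous covariates.

    Statistics are computed jointly over used and available candidates.
    Zero-SD covariates are dropped from the refit with a warning.
    """
    continuous = [c for c in spec.covariates if not c.startswith("lc_")]
    center, scale = {}, {}
    drop = []
    for col in continuous:
        sd = float(table[col].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            logger.warning("covariate %s has zero variance; dropped from refit", col)
            drop.append(col)
            continue
        center[col] = float(table[col].mean())
        scale[col] = 2.0 * sd
    recipe = StandardizationRecipe(center=center, scale=scale)
    std_table = recipe.transform(table)
    if drop:
        drop_blocks = {c.split("_")[-1] for c in drop}
        spec = ModelSpec(frozenset(spec.blocks - drop_blocks), spec.scale)
    return recipe, fit(spec, std_table)


@dataclass
class RSSContrast:
    """Relative selection strength between two covariate profiles."""

    x1: dict[str, float]
    x2: dict[str, float]
    log_rss: float
    rss: float


def log_rss(fit_result: FitResult, x1: dict[str, float], x2: dict[str, float]) -> RSSContrast:
    """log-RSS = beta'(x1 - x2); RSS = exp(log-RSS)."""
    missing = [c for c in fit_result.covariates if c not in x1 or c not in x2]
    if missing:
        raise ValueError(f"profiles missing covariate(s): {missing}")
    diff = np.array([x1[c] - x2[c] for c in fit_result.covariates])
    lr = float(fit_result.beta.to_numpy() @ diff)
    return RSSContrast(x1=dict(x1), x2=dict(x2), log_rss=lr, rss=float(np.exp(lr)))


def _base_profile(fit_result: FitResult, landcover: str = "NATIVE") -> dict[str, float]:
    prof = {c: 0.0 for c in fit_result.covariates}
    lc_col = f"lc_{landcover}"
    if lc_col in prof:
        prof[lc_col] = 1.0
    return prof


def crossing_contrast(
    fit_result: FitResult, feature: ConfigClass | str, n1: float = 1.0, n2: float = 0.0
) -> RSSContrast:
    """RSS of crossing a feature ``n1`` times vs ``n2`` times.

    Other linear features are held at 0 crossings in both profiles and land
    cover at NATIVE, so for a one-unit contrast RSS = exp(beta_feature).
    """
    col = f"n_cross_{ConfigClass(feature).value}"
    if col not in fit_result.covariates:
        raise ValueError(f"{col} not in fitted model")
    x1 = _base_profile(fit_result)
    x2 = _base_profile(fit_result)
    x1[col], x2[col] = n1, n2
    return log_rss(fit_result, x1, x2)


def range_vs_mean_curve(
    fit_result: FitResult,
    covariate: str,
    grid: np.ndarray,
    means: dict[str, float],
    landcover: str = "NATIVE",
) -> pd.DataFrame:
    """RSS sweeping one covariate over ``grid`` (location 1) vs its mean
    (location 2), other covariates at their means and land cover NATIVE."""
    if covariate not in fit_result.covariates:
        raise ValueError(f"{covariate} not in fitted model")
    x2 = _base_profile(fit_result, landcover)
    for c in fit_result.covariates:
        if not c.startswith("lc_"):
            x2[c] = float(means.get(c, 0.0))
    rows = []
    for val in np.asarray(grid, dtype=float):
        x1 = dict(x2)
        x1[covariate] = val
        contrast = log_rss(fit_result, x1, x2)
        rows.append((covariate, val, contrast.log_rss, contrast.rss))
    return pd.DataFrame(rows, columns=["covariate", "x", "log_rss", "rss"])
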