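"""Random-effects pooling, mixed-effects meta-regression, and bootstrap CIs.

Two parallel tracks mirror how the compiled database is analysed:

* **weighted** — inverse-variance meta-analysis on the ~81% of observations
  that report dispersion.  The marginal variance of effect i is
  se_i² + τ² (+ variance components for grouping factors such as biome or
  time class); τ² is estimated by REML (default) or the closed-form
  DerSimonian–Laird moment estimator, and fixed effects by GLS with Wald
  intervals.
* **unweighted** — a linear mixed model on the log response ratios with unit
  residual weighting, usable on the full database; uncertainty comes from
  non-parametric case bootstrap at the study level (resampling whole
  studies preserves within-study correlation).

Back-transformation to percent differences is applied to pooled estimates
and interval endpoints only — never to individual effects before pooling,
which would estimate a different (and biased) quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .effects import percent_difference

__all__ = [
    "BootstrapResult",
    "MetaFit",
    "bootstrap_ci",
    "estimate_stratum_effects",
    "fit_meta_regression",
    "pool_random_effects",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MetaFit:
    """A fitted pooled effect or meta-regression on the log-RR scale."""

    coefficients: pd.Series
    se_coefficients: pd.Series
    tau2: float
    random_terms: dict[str, float]
    ci: pd.DataFrame  # columns: lower, upper; index matches coefficients
    loglik: float
    aic: float
    n_effects: int
    mode: str  # "weighted" | "unweighted"
    method: str  # "DL" | "REML"
    sigma2: float | None = None  # unweighted residual variance

    @property
    def estimate(self) -> float:
        """Convenience accessor for intercept-only fits."""
        return float(self.coefficients.iloc[0])

    def back_transformed(self) -> pd.DataFrame:
        """Coefficient table on the percent-difference display scale.

        Meaningful for cell-means-style coefficients (per-level pooled
        effects); contrasts against a reference level stay on the log scale.
        """
        rows = {}
        for name in self.coefficients.index:
            rows[name] = {
                "percent_diff": percent_difference(float(self.coefficients[name])),
                "lower": percent_difference(float(self.ci.loc[name, "lower"])),
                "upper": percent_difference(float(self.ci.loc[name, "upper"])),
            }
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap interval for one statistic."""

    point: float
    lower: float
    upper: float
    n_boot: int
    seed: int
    unit: str
    n_failed: int = 0


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Closed-form DerSimonian–Laird moment estimate of τ²; returns (τ², Q)."""
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    k = len(y)
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    return float(tau2), q


def _restricted_loglik(
    y: np.ndarray, X: np.ndarray, V_diag: np.ndarray, ZZt: list[np.ndarray], vc: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """REML log-likelihood; returns (ll, beta, cov_beta).

    V = diag(V_diag) + Σ_g vc_g · Z_g Z_g'.  Fixed effects are profiled out
    by GLS.
    """
    n, p = X.shape
    V = np.diag(V_diag.astype(float))
    for s2, M in zip(vc, ZZt):
        V += s2 * M
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    XtViX = X.T @ Vi_X
    try:
        Lx = np.linalg.cholesky(XtViX)
    except np.linalg.LinAlgError:
        return -np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
    logdetXtViX = 2.0 * np.sum(np.log(np.diag(Lx)))
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    ll = -0.5 * ((n - p) * _LOG2PI + logdetV + logdetXtViX + quad)
    cov = np.linalg.inv(XtViX)
    return float(ll), beta, cov


def _fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    se2: np.ndarray | None,
    ZZt: list[np.ndarray],
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Maximise the restricted likelihood over the variance components.

    ``se2`` of None selects the unweighted parameterisation, where the first
    component is the residual variance σ² (times the identity); otherwise the
    first component is τ² added to the known diagonal se².
    Returns (varcomps, ll, beta, cov_beta); varcomps[0] is τ² or σ².
    """
    n = len(y)
    vary = max(float(np.var(y)), 1e-8)
    n_comp = 1 + len(ZZt)
    # first component is tau^2 (weighted) or sigma^2 (unweighted) on the identity
    mats = [np.eye(n)] + ZZt

    def nll(theta: np.ndarray) -> float:
        vc = theta
        base = se2 if se2 is not None else np.zeros(n)
        ll, _, _ = _restricted_loglik(y, X, np.asarray(base, float), mats, vc)
        return -ll if np.isfinite(ll) else 1e12

    lb = 1e-10 if se2 is None else 0.0
    x0 = np.full(n_comp, vary / n_comp)
    x0[0] = max(x0[0], 1e-6)
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(lb, 10.0 * vary + 1.0)] + [(0.0, 10.0 * vary + 1.0)] * (n_comp - 1),
    )
    if not res.success:
        warnings.warn(f"REML optimisation did not fully converge: {res.message}")
    vc = np.asarray(res.x, float)
    base = se2 if se2 is not None else np.zeros(n)
    ll, beta, cov = _restricted_loglik(y, X, np.asarray(base, float), mats, vc)
    return vc, ll, beta, cov


def pool_random_effects(
    effects: Sequence[float],
    se: Sequence[float],
    method: str = "DL",
    ci_level: float = 0.95,
) -> MetaFit:
    """Pool effect sizes under the random-effects model y_i ~ N(μ, se_i² + τ²).

    ``method="DL"`` uses the closed-form DerSimonian–Laird moment estimator
    of τ²; ``"REML"`` maximises the restricted likelihood iteratively and
    falls back to DL with a warning on non-convergence.  The pooled mean
    uses weights 1/(se_i² + τ̂²) with a Wald interval.
    """
    y = np.asarray(effects, dtype=float)
    s = np.asarray(se, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 effects to pool")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(s)) or np.any(s < 0):
        raise ValueError("effects must be finite, SEs finite and >= 0")
    if np.all(s == 0) and np.all(y == y[0]):
        # degenerate but well-defined: identical effects, no sampling error
        s = np.full_like(s, 1.0)
    elif np.all(s == 0):
        raise ValueError("all SEs are zero: inverse-variance weights are degenerate")
    elif np.any(s == 0):
        raise ValueError("zero SEs mixed with positive ones: weights are degenerate")
    v = s**2

    X = np.ones((len(y), 1))
    if method.upper() == "REML":
        try:
            vc, ll, beta, cov = _fit_reml(y, X, v, [])
            tau2 = float(vc[0])
        except Exception as exc:  # fall back to the moment estimator
            warnings.warn(f"REML failed ({exc}); falling back to DerSimonian-Laird")
            method = "DL"
    if method.upper() == "DL":
        tau2, _ = _dl_tau2(y, np.where(v > 0, v, 1e-12))
        ll, beta, cov = _restricted_loglik(y, X, v + tau2, [], np.array([]))
    mu = float(beta[0])
    se_mu = float(np.sqrt(cov[0, 0]))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    coefficients = pd.Series({"intercept": mu})
    se_coef = pd.Series({"intercept": se_mu})
    ci = pd.DataFrame(
        {"lower": [mu - z * se_mu], "upper": [mu + z * se_mu]}, index=["intercept"]
    )
    return MetaFit(
        coefficients=coefficients,
        se_coefficients=se_coef,
        tau2=float(tau2),
        random_terms={},
        ci=ci,
        loglik=float(ll),
        aic=float(-2 * ll + 2 * (1 + 1)),
        n_effects=len(y),
        mode="weighted",
        method=method.upper(),
    )


def _design_matrix(
    df: pd.DataFrame,
    fixed: Sequence[str],
    reference_levels: Mapping[str, str] | None,
    cell_means: bool,
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design: intercept + level-vs-reference contrasts, or, with
    ``cell_means``, one column per level of the single fixed factor."""
    reference_levels = dict(reference_levels or {})
    if cell_means:
        if len(fixed) != 1:
            raise ValueError("cell-means coding requires exactly one fixed factor")
        col = fixed[0]
        levels = list(pd.unique(df[col].dropna()))
        X = np.column_stack([(df[col] == lv).to_numpy(float) for lv in levels])
        names = [f"{col}[{lv}]" for lv in levels]
        return X, names
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for col in fixed:
        levels = sorted(pd.unique(df[col].dropna()), key=str)
        ref = reference_levels.get(col, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not found in {col}")
        for lv in levels:
            if lv == ref:
                continue
            cols.append((df[col] == lv).to_numpy(float))
            names.append(f"{col}[{lv}]")
    return np.column_stack(cols), names


def _grouping_matrices(
    df: pd.DataFrame, random: Sequence[str]
) -> tuple[list[np.ndarray], list[str]]:
    ZZt, used = [], []
    for col in random:
        levels = pd.unique(df[col].dropna())
        if len(levels) < 2:
            warnings.warn(f"random factor {col!r} has a single level; dropped")
            continue
        Z = np.column_stack([(df[col] == lv).to_numpy(float) for lv in levels])
        ZZt.append(Z @ Z.T)
        used.append(col)
    return ZZt, used


def fit_meta_regression(
    df: pd.DataFrame,
    fixed: Sequence[str] = (),
    random: Sequence[str] = (),
    mode: str = "weighted",
    method: str = "REML",
    effect_col: str = "rr",
    se_col: str = "se_rr",
    include_study: bool | None = None,
    study_col: str = "study_id",
    reference_levels: Mapping[str, str] | None = None,
    cell_means: bool = False,
    ci_level: float = 0.95,
) -> MetaFit:
    """Mixed-effects meta-regression of log response ratios on moderators.

    ``fixed`` are categorical moderator columns entering as dummy-coded
    fixed effects (level-vs-reference contrasts, or per-level cell means
    with ``cell_means=True``); ``random`` are grouping factors contributing
    variance components to the marginal covariance.

    Weighted mode requires a finite positive ``se_col`` on every row and
    models marginal variance se² + τ² + Σ components; unweighted mode fits
    the same structure with a free residual variance σ² and unit weights.
    ``include_study`` adds a study random intercept (default: on for the
    unweighted track, off for the weighted one).
    """
    if mode not in ("weighted", "unweighted"):
        raise ValueError("mode must be 'weighted' or 'unweighted'")
    work = df.loc[np.isfinite(df[effect_col].to_numpy(dtype=float))].reset_index(
        drop=True
    )
    if include_study is None:
        include_study = mode == "unweighted"
    y = work[effect_col].to_numpy(dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 effects")
    if mode == "weighted":
        s = work[se_col].to_numpy(dtype=float)
        if np.any(~np.isfinite(s)) or np.any(s <= 0):
            raise ValueError("weighted mode requires finite se_rr > 0 on every row")
        se2 = s**2
    else:
        se2 = None

    X, names = _design_matrix(work, list(fixed), reference_levels, cell_means)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        aliased = [names[i] for i in range(len(diag)) if diag[i] < 1e-10]
        raise ValueError(
            f"design matrix is rank deficient; aliased columns: {aliased or names}"
        )

    rand_cols = list(random)
    if include_study and study_col in work.columns:
        rand_cols = rand_cols + [study_col]
    ZZt, used = _grouping_matrices(work, rand_cols)

    vc, ll, beta, cov = _fit_reml(y, X, se2, ZZt)
    if se2 is not None:
        tau2, sigma2 = float(vc[0]), None
    else:
        sigma2, tau2 = float(vc[0]), 0.0
    random_terms = {name: float(v) for name, v in zip(used, vc[1:])}

    se_beta = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    coefficients = pd.Series(beta, index=names)
    n_par = X.shape[1] + len(vc)
    return MetaFit(
        coefficients=coefficients,
        se_coefficients=pd.Series(se_beta, index=names),
        tau2=tau2,
        random_terms=random_terms,
        ci=pd.DataFrame(
            {"lower": beta - z * se_beta, "upper": beta + z * se_beta}, index=names
        ),
        loglik=float(ll),
        aic=float(-2 * ll + 2 * n_par),
        n_effects=len(y),
        mode=mode,
        method="REML",
        sigma2=sigma2,
    )


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    df: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    unit: str = "study",
    study_col: str = "study_id",
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Non-parametric case-resampling bootstrap percentile interval.

    ``unit="study"`` resamples whole studies with replacement (preserving
    within-study correlation); ``unit="observation"`` resamples rows.
    Replicates whose statistic raises or is non-finite are dropped and
    counted; more than 10% failures warns, total failure raises.
    Deterministic under a fixed seed.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    if unit not in ("study", "observation"):
        raise ValueError("unit must be 'study' or 'observation'")
    rng = np.random.default_rng(seed)
    df = df.reset_index(drop=True)
    if unit == "study":
        groups = [idx.to_numpy() for _, idx in df.groupby(study_col).groups.items()]
    else:
        groups = [np.array([i]) for i in range(len(df))]
    n_groups = len(groups)

    point = float(statistic(df))
    values = np.empty(n_boot)
    n_failed = 0
    for b in range(n_boot):
        chosen = rng.integers(0, n_groups, size=n_groups)
        idx = np.concatenate([groups[j] for j in chosen])
        try:
            val = float(statistic(df.iloc[idx]))
        except Exception:
            val = np.nan
        if not np.isfinite(val):
            n_failed += 1
            values[b] = np.nan
        else:
            values[b] = val
    ok = values[np.isfinite(values)]
    if len(ok) == 0:
        raise RuntimeError("all bootstrap replicates failed")
    if n_failed > 0.1 * n_boot:
        warnings.warn(f"{n_failed}/{n_boot} bootstrap replicates failed")
    alpha = 1.0 - ci_level
    lower, upper = np.quantile(ok, [alpha / 2, 1 - alpha / 2])
    if not (lower <= point <= upper):
        warnings.warn(
            "bootstrap percentile interval does not bracket the point estimate "
            "(heavy skew or instability)"
        )
    return BootstrapResult(
        point=point,
        lower=float(lower),
        upper=float(upper),
        n_boot=n_boot,
        seed=seed,
        unit=unit,
        n_failed=n_failed,
    )


def estimate_stratum_effects(
    df: pd.DataFrame,
    by: Sequence[str] = ("pool", "treatment", "biome"),
    mode: str = "unweighted",
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    min_k: int = 3,
    effect_col: str = "rr",
    se_col: str = "se_rr",
) -> pd.DataFrame:
    """Per-stratum pooled percent differences with CIs.

    Unweighted track: the stratum mean log-RR, with a study-level bootstrap
    percentile interval.  Weighted track: REML random-effects pooling of the
    rows that carry dispersion, with a Wald interval.  Estimates and
    interval endpoints are back-transformed to percent differences *after*
    pooling; strata with fewer than ``min_k`` usable effects are flagged as
    insufficient rather than fitted.
    """
    if mode not in ("weighted", "unweighted"):
        raise ValueError("mode must be 'weighted' or 'unweighted'")
    rows = []
    work = df.loc[np.isfinite(df[effect_col].to_numpy(dtype=float))]
    for key, sub in work.groupby(list(by), observed=True, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        base = dict(zip(by, key))
        base["mode"] = mode
        if mode == "weighted":
            sub = sub.loc[np.isfinite(sub[se_col].to_numpy(dtype=float)) & (sub[se_col] > 0)]
        base["k"] = len(sub)
        if len(sub) < min_k:
            base.update(
                estimate_rr=np.nan,
                percent_diff=np.nan,
                lower=np.nan,
                upper=np.nan,
                significant=False,
                insufficient=True,
            )
            rows.append(base)
            continue
        if mode == "weighted":
            fit = pool_random_effects(
                sub[effect_col], sub[se_col], method="REML", ci_level=ci_level
            )
            est = fit.estimate
            lo = float(fit.ci.iloc[0]["lower"])
            hi = float(fit.ci.iloc[0]["upper"])
        else:
            boot = bootstrap_ci(
                lambda d: d[effect_col].mean(),
                sub,
                n_boot=n_boot,
                seed=seed,
                unit="study",
                ci_level=ci_level,
            )
            est, lo, hi = boot.point, boot.lower, boot.upper
        base.update(
            estimate_rr=est,
            percent_diff=percent_difference(est),
            lower=percent_difference(lo),
            upper=percent_difference(hi),
            significant=not (lo <= 0.0 <= hi),
            insufficient=False,
        )
        rows.append(base)
    return pd.DataFrame(rows)
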