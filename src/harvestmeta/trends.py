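"""Time-since-treatment trend models with information-criterion selection.

Carbon recovery after harvest is modelled on the log-response-ratio scale
against continuous time since the most recent cut, separately per harvest
treatment.  Candidate families:

* ``linear``     — rr = b0 + b1·t
* ``cubic``      — a single cubic polynomial in t
* ``spline``     — a restricted (natural) cubic spline with interior knots
                   at time quantiles {0.25, 0.5, 0.75}
* ``intercept``  — no time dependence (the null family)

Fits are ordinary or inverse-variance-weighted least squares; selection
keeps the candidates that are *significant* and among them picks the lowest
corrected AIC (AICc by default — the per-treatment subsets here hold a few
dozen effects, where the small-sample correction matters; plain AIC via
``criterion="aic"``).  Significance follows the hierarchy principle of
polynomial regression: a family counts as significant only if the terms it
adds beyond the largest simpler candidate nested within it are jointly
significant, so a cubic is never retained on the strength of its linear
part alone.

Fitting on the log scale keeps back-transformed predictions above −100%
automatically; undefined effects (zero treatment means) are excluded from
log-scale fits and surface only in the binned display profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import DEFAULT_TIME_BINS, assign_time_class
from .meta import bootstrap_ci
from .effects import percent_difference

__all__ = [
    "FAMILIES",
    "TrendFit",
    "binned_time_profile",
    "crossing_time",
    "fit_time_trend",
    "select_trend_model",
]

FAMILIES = ("intercept", "linear", "cubic", "spline")


def _natural_spline_basis(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (Harrell's truncated-power form).

    With m knots k_1 < ... < k_m the basis has m−1 columns: t itself plus
    m−2 nonlinear terms, linear beyond the boundary knots.
    """
    k = np.asarray(knots, dtype=float)
    m = len(k)
    if m < 3:
        raise ValueError("a restricted cubic spline needs at least 3 knots")

    def tp(x):  # truncated third power
        return np.where(x > 0, x**3, 0.0)

    cols = [t]
    denom = k[-1] - k[0]
    for j in range(m - 2):
        col = (
            tp(t - k[j])
            - tp(t - k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
            + tp(t - k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2])
        ) / denom**2
        cols.append(col)
    return np.column_stack(cols)


def _design(t: np.ndarray, family: str, knots: np.ndarray | None) -> np.ndarray:
    if family == "intercept":
        base = np.empty((len(t), 0))
    elif family == "linear":
        base = t[:, None]
    elif family == "cubic":
        base = np.column_stack([t, t**2, t**3])
    elif family == "spline":
        base = _natural_spline_basis(t, knots)
    else:
        raise ValueError(f"unknown trend family {family!r}; allowed: {FAMILIES}")
    return sm.add_constant(base, has_constant="add")


@dataclass
class TrendFit:
    """A fitted time-trend for one treatment's effect sizes."""

    family: str
    coefficients: np.ndarray
    knots: np.ndarray | None
    aic: float
    aicc: float
    loglik: float
    p_joint: float  # joint F-test of all non-intercept terms (1.0 for intercept)
    weighted: bool
    n: int
    t_range: tuple[float, float]
    treatment: str = ""
    _res: object = field(default=None, repr=False, compare=False)

    def predict(self, t: float | np.ndarray) -> np.ndarray:
        """Predicted log response ratio at time t (clamped to the fitted range)."""
        t = np.clip(np.asarray(t, dtype=float), *self.t_range)
        X = _design(np.atleast_1d(t), self.family, self.knots)
        return X @ self.coefficients

    def predict_percent(self, t: float | np.ndarray) -> np.ndarray:
        return (np.exp(self.predict(t)) - 1.0) * 100.0


def fit_time_trend(
    time: Sequence[float],
    effects: Sequence[float],
    family: str = "linear",
    weights: Sequence[float] | None = None,
    knots: Sequence[float] | None = None,
    treatment: str = "",
) -> TrendFit:
    """Least-squares fit of log response ratios against time for one family.

    ``weights`` are inverse-variance weights (1/se²) for the weighted
    meta-regression track; None fits ordinary least squares.  Spline knots
    default to the {0.25, 0.5, 0.75} time quantiles and must lie inside the
    data range.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(effects, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        ok &= np.isfinite(w) & (w > 0)
        w = w[ok]
    t, y = t[ok], y[ok]
    if len(t) < 5:
        raise ValueError("need at least 5 effects with finite time")
    if family == "spline":
        if knots is None:
            knots = np.quantile(t, [0.25, 0.5, 0.75])
            knots = np.unique(knots)
        knots = np.asarray(knots, dtype=float)
        if np.any(knots < t.min()) or np.any(knots > t.max()):
            raise ValueError("spline knots must lie inside the data range")
        if len(knots) < 3:
            raise ValueError("degenerate time distribution: fewer than 3 distinct knots")
    else:
        knots = None
    X = _design(t, family, knots)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"{family} family has {X.shape[1]} parameters but only {X.shape[0]} points"
        )
    model = sm.WLS(y, X, weights=w) if weights is not None else sm.OLS(y, X)
    res = model.fit()
    n, p = X.shape
    n_par = p + 1  # + residual variance
    aic = float(res.aic)
    denom = n - n_par - 1
    aicc = aic + (2.0 * n_par * (n_par + 1) / denom if denom > 0 else np.inf)
    if p > 1:
        contrast = np.zeros((p - 1, p))
        contrast[:, 1:] = np.eye(p - 1)
        p_joint = float(res.f_test(contrast).pvalue)
    else:
        p_joint = 1.0
    return TrendFit(
        family=family,
        coefficients=np.asarray(res.params, dtype=float),
        knots=knots,
        aic=aic,
        aicc=float(aicc),
        loglik=float(res.llf),
        p_joint=p_joint,
        weighted=weights is not None,
        n=n,
        t_range=(float(t.min()), float(t.max())),
        treatment=treatment,
        _res=res,
    )


def select_trend_model(
    time: Sequence[float],
    effects: Sequence[float],
    families: Sequence[str] = ("linear", "cubic"),
    weights: Sequence[float] | None = None,
    alpha: float = 0.05,
    criterion: str = "aicc",
    treatment: str = "",
) -> tuple[TrendFit, pd.DataFrame]:
    """Fit all candidate families and keep the best significant one.

    A family is significant when the terms it adds beyond the largest
    simpler candidate nested in it pass a joint F-test at ``alpha`` (the
    hierarchy principle: a cubic must justify its curvature terms, not ride
    on its linear part).  Among significant families the lowest criterion
    (AICc by default) wins; if none is significant, the intercept-only fit
    is returned with a diagnostic.  Returns (winner, comparison table).
    """
    if len(families) < 2 and tuple(families) != ("intercept",):
        raise ValueError("need at least 2 candidate families")
    fits: list[TrendFit] = []
    errors: list[str] = []
    for fam in families:
        try:
            fits.append(
                fit_time_trend(time, effects, fam, weights=weights, treatment=treatment)
            )
        except Exception as exc:
            errors.append(f"{fam}: {exc}")
    if not fits:
        raise RuntimeError("all candidate fits failed: " + "; ".join(errors))
    fitted_families = {f.family for f in fits}
    p_added = [_added_terms_pvalue(f, fitted_families) for f in fits]
    table = pd.DataFrame(
        {
            "family": [f.family for f in fits],
            "aic": [f.aic for f in fits],
            "aicc": [f.aicc for f in fits],
            "loglik": [f.loglik for f in fits],
            "p_joint": [f.p_joint for f in fits],
            "p_added": p_added,
            "n": [f.n for f in fits],
        }
    )
    key = "aicc" if criterion == "aicc" else "aic"
    table["significant"] = table["p_added"] < alpha
    survivors = [f for f, p in zip(fits, p_added) if p < alpha]
    if not survivors:
        winner = fit_time_trend(
            time, effects, "intercept", weights=weights, treatment=treatment
        )
        table.attrs["diagnostic"] = "no candidate significant; intercept-only returned"
        return winner, table
    winner = min(survivors, key=lambda f: getattr(f, key))
    table.attrs["diagnostic"] = ""
    return winner, table


def _added_terms_pvalue(fit: TrendFit, fitted_families: set[str]) -> float:
    """Joint F-test p-value of the terms a family adds over its nested parent.

    ``linear`` adds the slope over the intercept; ``cubic`` and ``spline``
    add their nonlinear columns over ``linear`` when linear is among the
    candidates, otherwise over the intercept.  Design matrices share their
    leading columns, so the test is a Wald F on the trailing coefficients.
    """
    p = len(fit.coefficients)
    if fit.family == "intercept" or p <= 1:
        return 1.0
    if fit.family == "linear":
        start = 1
    else:
        start = 2 if "linear" in fitted_families else 1
    if p <= start:
        return 1.0
    contrast = np.zeros((p - start, p))
    contrast[:, start:] = np.eye(p - start)
    return float(fit._res.f_test(contrast).pvalue)


def crossing_time(
    fit_a: TrendFit,
    fit_b: TrendFit,
    t_min: float | None = None,
    t_max: float | None = None,
    n_grid: int = 2001,
) -> float | None:
    """First time at which two fitted trend curves cross, or None.

    Scans a dense grid of the overlapping fitted range for a sign change of
    the difference and bisects the bracketing interval.
    """
    lo = max(fit_a.t_range[0], fit_b.t_range[0]) if t_min is None else t_min
    hi = min(fit_a.t_range[1], fit_b.t_range[1]) if t_max is None else t_max
    if hi <= lo:
        return None
    grid = np.linspace(lo, hi, n_grid)
    diff = fit_a.predict(grid) - fit_b.predict(grid)
    sign = np.sign(diff)
    changes = np.flatnonzero(np.diff(sign) != 0)
    if len(changes) == 0:
        return None
    i = changes[0]
    a, b = grid[i], grid[i + 1]
    for _ in range(60):
        m = 0.5 * (a + b)
        fm = float((fit_a.predict(m) - fit_b.predict(m))[0])
        fa = float((fit_a.predict(a) - fit_b.predict(a))[0])
        if fa * fm <= 0:
            b = m
        else:
            a = m
    return float(0.5 * (a + b))


def binned_time_profile(
    df: pd.DataFrame,
    bins: Sequence[float] = DEFAULT_TIME_BINS,
    by: Sequence[str] = ("treatment", "pool"),
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    min_k: int = 3,
) -> pd.DataFrame:
    """Per time-bin mean percent differences with bootstrap CIs.

    Within each stratum × time class: the unweighted mean log-RR with a
    study-level bootstrap percentile interval, back-transformed for display.
    Undefined effects (zero treatment mean) do not enter the log-scale mean;
    they are counted per bin and shown as −100% display rows only when a bin
    contains nothing else.  Empty bins are reported empty, not interpolated.
    """
    work = df.copy()
    work["time_class"] = assign_time_class(work["time_since_treatment"], bins)
    rows = []
    group_cols = list(by) + ["time_class"]
    for key, sub in work.groupby(group_cols, observed=True, sort=True):
        base = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        defined = sub.loc[sub["defined"].astype(bool)] if "defined" in sub else sub
        defined = defined.loc[np.isfinite(defined["rr"].to_numpy(dtype=float))]
        n_zero = int(len(sub) - len(defined))
        base["k"] = len(sub)
        base["k_undefined"] = n_zero
        if len(defined) < min_k:
            if len(defined) == 0 and n_zero > 0:
                # display-only bin: every stand lost the whole pool
                base.update(percent_diff=-100.0, lower=np.nan, upper=np.nan)
            else:
                base.update(percent_diff=np.nan, lower=np.nan, upper=np.nan)
            base["insufficient"] = True
            rows.append(base)
            continue
        boot = bootstrap_ci(
            lambda d: d["rr"].mean(),
            defined,
            n_boot=n_boot,
            seed=seed,
            unit="study",
            ci_level=ci_level,
        )
        base.update(
            percent_diff=percent_difference(boot.point),
            lower=percent_difference(boot.lower),
            upper=percent_difference(boot.upper),
            insufficient=False,
        )
        rows.append(base)
    return pd.DataFrame(rows)
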