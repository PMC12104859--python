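"""Effect sizes: log response ratios, their delta-method SEs, and conversions.

The effect size throughout is the log response ratio

    RR = ln(X̄_T / X̄_C),

the natural log of the ratio of the treated stand's mean carbon stock to the
reference stand's.  Its sampling SE follows from the delta method,

    SE(RR) = sqrt( SE(X̄_T)² / X̄_T²  +  SE(X̄_C)² / X̄_C² ),

i.e. the root sum of squared coefficients of variation of the two arms.  For
display, RR back-transforms to a percent difference relative to the
reference, (e^RR − 1)·100.

A clearcut stand measured immediately after harvest can hold zero live-tree
carbon; ln(0) is undefined, so such observations carry ``defined=False`` and
a display value of −100%.  They are excluded from all log-scale model
fitting and appear only in binned summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectSize",
    "add_effect_sizes",
    "allometric_biomass",
    "biomass_to_carbon",
    "compute_rr",
    "compute_se_rr",
    "percent_difference",
    "rr_from_percent",
]

#: default biomass -> carbon conversion factor (half of dry biomass is carbon)
CARBON_FRACTION = 0.5


@dataclass(frozen=True)
class EffectSize:
    """A log response ratio with optional SE and its display back-transform."""

    rr: float
    se_rr: float | None = None
    defined: bool = True

    @property
    def percent_diff(self) -> float:
        if not self.defined:
            return -100.0
        return percent_difference(self.rr)


def compute_rr(mean_treatment: float, mean_control: float) -> EffectSize:
    """Log response ratio of a treated mean against its reference mean.

    A zero treatment mean yields an undefined RR (``defined=False``,
    percent difference −100); a non-positive control mean is a domain error.
    """
    if not mean_control > 0:
        raise ValueError(
            "mean_control must be > 0: it is the denominator of the log response ratio"
        )
    if mean_treatment < 0:
        raise ValueError("mean_treatment must be >= 0")
    if mean_treatment == 0:
        return EffectSize(rr=math.nan, defined=False)
    return EffectSize(rr=math.log(mean_treatment / mean_control))


def compute_se_rr(
    mean_treatment: float,
    se_treatment: float,
    mean_control: float,
    se_control: float,
) -> float:
    """Delta-method SE of the log response ratio.

    Depends on each arm only through its coefficient of variation
    SE(X̄)/X̄, so rescaling both mean and SE of an arm leaves it unchanged.
    """
    if not (mean_treatment > 0 and mean_control > 0):
        raise ValueError("both means must be > 0 to compute SE(RR)")
    if se_treatment < 0 or se_control < 0:
        raise ValueError("standard errors must be >= 0")
    return math.sqrt(
        (se_treatment / mean_treatment) ** 2 + (se_control / mean_control) ** 2
    )


def percent_difference(rr: float) -> float:
    """Back-transform a log response ratio to percent difference, (e^rr − 1)·100."""
    if not math.isfinite(rr):
        raise ValueError("rr must be finite")
    return (math.exp(rr) - 1.0) * 100.0


def rr_from_percent(pd_value: float) -> float:
    """Inverse of :func:`percent_difference`, defined on (−100, ∞)."""
    if pd_value <= -100.0:
        raise ValueError("percent difference must exceed -100")
    return math.log(1.0 + pd_value / 100.0)


def biomass_to_carbon(biomass: float, fraction: float = CARBON_FRACTION) -> float:
    """Convert dry biomass (Mg ha⁻¹) to carbon (Mg C ha⁻¹) by a fixed fraction."""
    if biomass < 0:
        raise ValueError("biomass must be >= 0")
    return fraction * biomass


def allometric_biomass(
    dbh: float,
    coefficients: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> float:
    """Evaluate power-law allometry ``a * dbh^b`` per component and sum.

    ``coefficients`` maps component names (wood, bark, foliage, ...) to
    ``(a, b)`` pairs, or is a bare sequence of pairs.  Coefficients must be
    supplied by the caller — no species table is bundled and nothing is
    silently defaulted.
    """
    if dbh <= 0:
        raise ValueError("dbh must be > 0")
    if coefficients is None or len(coefficients) == 0:
        raise ValueError("allometric coefficients are required; none were supplied")
    pairs = (
        coefficients.values() if isinstance(coefficients, Mapping) else coefficients
    )
    total = 0.0
    for pair in pairs:
        a, b = pair
        total += a * dbh**b
    return total


def add_effect_sizes(df: pd.DataFrame) -> pd.DataFrame:
    """Append ``rr``, ``se_rr``, ``percent_diff`` and ``defined`` columns.

    Vectorised over an observation table with ``mean_treatment``,
    ``mean_control`` and optional ``se_*`` columns.  Zero treatment means
    produce ``defined=False`` rows with percent_diff −100 and NaN rr.
    """
    out = df.copy()
    mt = out["mean_treatment"].to_numpy(dtype=float)
    mc = out["mean_control"].to_numpy(dtype=float)
    if np.any(~(mc > 0)):
        bad = np.flatnonzero(~(mc > 0))
        raise ValueError(f"mean_control must be > 0; offending rows: {bad.tolist()}")
    defined = mt > 0
    rr = np.full(len(out), np.nan)
    rr[defined] = np.log(mt[defined] / mc[defined])
    se_rr = np.full(len(out), np.nan)
    if "se_treatment" in out.columns and "se_control" in out.columns:
        st = out["se_treatment"].to_numpy(dtype=float)
        sc = out["se_control"].to_numpy(dtype=float)
        ok = defined & ~np.isnan(st) & ~np.isnan(sc)
        se_rr[ok] = np.sqrt((st[ok] / mt[ok]) ** 2 + (sc[ok] / mc[ok]) ** 2)
    pdiff = np.where(defined, (np.exp(rr) - 1.0) * 100.0, -100.0)
    out["rr"] = rr
    out["se_rr"] = se_rr
    out["percent_diff"] = pdiff
    out["defined"] = defined
    return out
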