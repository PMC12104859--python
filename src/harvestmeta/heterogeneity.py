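"""Hedges–Olkin heterogeneity decomposition and hierarchical moderator selection.

For k effect sizes y_i with weights w_i (inverse-variance 1/SE² when
dispersion is reported, unit weights on the unweighted track), total
heterogeneity about the weighted grand mean ȳ is

    Q_total = Σ w_i (y_i − ȳ)²,

and for a categorical moderator with groups g,

    Q_within  = Σ_g Σ_{i∈g} w_i (y_i − ȳ_g)²,
    Q_between = Q_total − Q_within,

with Q_between referred to a χ² distribution on (number of groups − 1)
degrees of freedom.  A moderator with a large, significant Q_between
explains real variation in effect size.

The hierarchical selection mirrors an ANOVA-style variance partitioning run
iteratively: test every candidate moderator on the full data, split on the
strongest significant one, and repeat inside each subgroup until nothing
further is significant or a subgroup is too small to test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_CANDIDATE_ORDER",
    "HeterogeneityResult",
    "PartitionNode",
    "hierarchical_partition",
    "q_decomposition",
]

#: deterministic tie-break order for candidate moderators
DEFAULT_CANDIDATE_ORDER = ("pool", "treatment", "time_class", "biome", "reference_type")


@dataclass(frozen=True)
class HeterogeneityResult:
    """Q-statistic decomposition of effect-size heterogeneity for one moderator."""

    moderator: str
    q_total: float
    q_within: float
    q_between: float
    df_between: int
    p_value: float
    k: int
    levels: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def q_decomposition(
    effects: Sequence[float],
    weights: Sequence[float] | None,
    groups: Sequence,
    moderator: str = "",
) -> HeterogeneityResult:
    """Partition Q_total into within- and between-group components.

    ``weights`` of None means unit weights (the unweighted analysis track).
    Empty groups are dropped with a warning.  If all effects are identical
    the decomposition is the zero vector with p = 1.
    """
    y = np.asarray(effects, dtype=float)
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 effect sizes")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("effects must be finite and weights finite and > 0")
    g = pd.Series(list(groups))
    if len(g) != len(y):
        raise ValueError("groups must match effects in length")
    if g.isna().any():
        keep = ~g.isna().to_numpy()
        warnings.warn("dropping effects with missing group label")
        y, w, g = y[keep], w[keep], g[keep].reset_index(drop=True)
    levels = [lv for lv in pd.unique(g)]
    if len(levels) < 2:
        raise ValueError("need at least 2 non-empty groups")

    grand = float(np.sum(w * y) / np.sum(w))
    q_total = float(np.sum(w * (y - grand) ** 2))
    q_within = 0.0
    for lv in levels:
        m = (g == lv).to_numpy()
        gm = float(np.sum(w[m] * y[m]) / np.sum(w[m]))
        q_within += float(np.sum(w[m] * (y[m] - gm) ** 2))
    q_between = max(0.0, q_total - q_within)
    df_between = len(levels) - 1
    p = float(stats.chi2.sf(q_between, df_between))
    return HeterogeneityResult(
        moderator=moderator,
        q_total=q_total,
        q_within=q_within,
        q_between=q_between,
        df_between=df_between,
        p_value=p,
        k=len(y),
        levels=tuple(str(lv) for lv in levels),
    )


@dataclass
class PartitionNode:
    """One node of the hierarchical moderator-selection tree."""

    n: int
    moderator: str | None = None  # None -> leaf
    results: dict[str, HeterogeneityResult] = field(default_factory=dict)
    children: dict[str, "PartitionNode"] = field(default_factory=dict)
    diagnostic: str = ""

    @property
    def is_leaf(self) -> bool:
        return self.moderator is None

    def leaves(self) -> list["PartitionNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children.values():
            out.extend(child.leaves())
        return out

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "moderator": self.moderator,
            "diagnostic": self.diagnostic,
            "tests": {
                name: {
                    "q_total": r.q_total,
                    "q_within": r.q_within,
                    "q_between": r.q_between,
                    "df_between": r.df_between,
                    "p_value": r.p_value,
                    "k": r.k,
                }
                for name, r in self.results.items()
            },
        }
        if self.children:
            d["children"] = {lv: c.to_dict() for lv, c in self.children.items()}
        return d


def hierarchical_partition(
    df: pd.DataFrame,
    candidates: Sequence[str] = DEFAULT_CANDIDATE_ORDER,
    alpha: float = 0.05,
    weight_col: str | None = None,
    effect_col: str = "rr",
    min_group_size: int = 3,
) -> PartitionNode:
    """Iteratively split the data on the strongest significant moderator.

    At every node each remaining candidate is tested by
    :func:`q_decomposition`; the candidate with the largest significant
    Q_between (p < ``alpha``) wins, ties broken by the order of
    ``candidates``.  Subgroups smaller than ``min_group_size`` become
    "insufficient data" leaves.  Deterministic for a fixed candidate order.

    ``df`` must carry ``effect_col`` plus the candidate columns;
    ``weight_col`` of None selects unit weights.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    candidates = [c for c in candidates if c in df.columns]
    if not candidates:
        raise ValueError("no candidate column present in the data")
    work = df.loc[np.isfinite(df[effect_col].to_numpy(dtype=float))]
    return _partition_node(
        work, list(candidates), alpha, weight_col, effect_col, min_group_size
    )


def _partition_node(
    df: pd.DataFrame,
    candidates: list[str],
    alpha: float,
    weight_col: str | None,
    effect_col: str,
    min_group_size: int,
) -> PartitionNode:
    node = PartitionNode(n=len(df))
    if len(df) < max(2, min_group_size):
        node.diagnostic = "insufficient data"
        return node
    if not candidates:
        node.diagnostic = "no remaining candidates"
        return node

    y = df[effect_col].to_numpy(dtype=float)
    w = df[weight_col].to_numpy(dtype=float) if weight_col else None
    best_name, best = None, None
    for cand in candidates:
        g = df[cand]
        if g.nunique(dropna=True) < 2:
            continue
        try:
            res = q_decomposition(y, w, g, moderator=cand)
        except ValueError:
            continue
        node.results[cand] = res
        if res.p_value < alpha and (best is None or res.q_between > best.q_between):
            best_name, best = cand, res
    if best_name is None:
        node.diagnostic = "no significant moderator"
        return node

    node.moderator = best_name
    remaining = [c for c in candidates if c != best_name]
    for lv, sub in df.groupby(best_name, observed=True, sort=False):
        if len(sub) < min_group_size:
            child = PartitionNode(n=len(sub), diagnostic="insufficient data")
        else:
            child = _partition_node(
                sub, remaining, alpha, weight_col, effect_col, min_group_size
            )
        node.children[str(lv)] = child
    return node
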