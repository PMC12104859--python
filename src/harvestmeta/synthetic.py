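"""Synthetic harvest-carbon databases with known generative truth.

The generator emulates the statistical structure of the compiled field
database so that every downstream stage — effect sizes, heterogeneity
partitioning, meta-regression, bootstrap, trend selection — has a truth to
recover:

* a stratified design over 6 carbon pools × 2 harvest treatments × 2 biomes,
  with the same stratum imbalance as the compiled literature (boreal rows
  are ~43% of the total but only ~10% of them are partial cuts; live trees
  are the best-covered pool, understory the worst);
* per-stratum true log response ratios θ, constant or following a named
  time trajectory (linear recovery for partial cuts, steep-then-saturating
  recovery for clearcuts, U-shaped deadwood accumulation);
* between-study heterogeneity: each study carries an effect shift
  b_s ~ N(0, τ²) shared by all its observations;
* within-study sampling error on the arithmetic scale: arm means are drawn
  Normal around their expected stock with SD = cv · mean (truncated at
  zero), and the reported SE is the true SD/√n of the drawn replicate count;
* variance-information missingness: a configurable fraction of rows is
  stripped of SE and n, mirroring the ~19% of published observations that
  report no dispersion.

The defaults (:func:`default_config`) encode the compiled database's
composition: 61 studies, ≈558 observations, time-since-treatment medians of
15 y (clearcut, max 110) and 9 y (partial, max 50), reference stocks per
pool summing to ≈224 Mg C ha⁻¹, and stratum effects matching the headline
estimates (−78%/−45% live trees, −21% temperate clearcut forest floor,
+121% understory, U-shaped coarse woody debris from +136% down to −68%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data_model import BIOMES, POOLS, TREATMENTS, Dataset

__all__ = [
    "SyntheticConfig",
    "Trajectory",
    "GenerativeTruth",
    "default_config",
    "generate_dataset",
    "trajectory_value",
]

TRAJECTORY_SHAPES = ("constant", "linear", "saturating", "u_shaped")


@dataclass(frozen=True)
class Trajectory:
    """A named time-trajectory of the true log response ratio θ(t).

    shapes and parameters
    ---------------------
    constant:    ``theta``                        θ(t) = theta
    linear:      ``theta0, slope``                θ(t) = theta0 + slope·t
    saturating:  ``floor, scale``                 θ(t) = floor·exp(−t/scale),
                 rising from a deep deficit toward the reference (θ=0)
    u_shaped:    ``theta0, theta_min, t_min``     quadratic through (0, theta0)
                 with vertex (t_min, theta_min); crosses from positive to
                 negative and back — the deadwood pulse-then-deficit arc
    """

    shape: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape not in TRAJECTORY_SHAPES:
            raise ValueError(
                f"unknown trajectory shape {self.shape!r}; allowed: {TRAJECTORY_SHAPES}"
            )
        n_expected = {"constant": 1, "linear": 2, "saturating": 2, "u_shaped": 3}
        if len(self.params) != n_expected[self.shape]:
            raise ValueError(
                f"{self.shape} trajectory takes {n_expected[self.shape]} parameter(s)"
            )

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return trajectory_value(self.shape, self.params, t)


def trajectory_value(
    shape: str, params: tuple[float, ...], t: float | np.ndarray
) -> float | np.ndarray:
    """Evaluate a named trajectory θ(t) at time t ≥ 0 (years)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since treatment must be >= 0")
    if shape == "constant":
        (theta,) = params
        out = np.full_like(t, theta)
    elif shape == "linear":
        theta0, slope = params
        out = theta0 + slope * t
    elif shape == "saturating":
        floor, scale = params
        out = floor * np.exp(-t / scale)
    elif shape == "u_shaped":
        theta0, theta_min, t_min = params
        out = theta_min + (theta0 - theta_min) * ((t - t_min) / t_min) ** 2
    else:
        raise ValueError(f"unknown trajectory shape {shape!r}")
    return out.item() if out.ndim == 0 else out


def linear_from_percents(pd0: float, pd1: float, t1: float) -> Trajectory:
    """Linear trajectory calibrated through percent differences at t=0 and t=t1."""
    th0 = math.log(1 + pd0 / 100.0)
    th1 = math.log(1 + pd1 / 100.0)
    return Trajectory("linear", (th0, (th1 - th0) / t1))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative truth for a synthetic harvest-carbon database."""

    n_studies: int = 61
    obs_per_study: tuple[int, int] = (4, 14)  # inclusive range, drawn per study
    true_effects: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    time_model: Mapping[tuple[str, str], Trajectory] = field(default_factory=dict)
    tau: float = 0.2
    control_mean_range: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    cv_within: float = 0.3
    n_reps_range: tuple[int, int] = (3, 10)
    missing_variance_rate: float = 0.19
    #: P(biome = boreal) and P(partial | biome)
    biome_shares: Mapping[str, float] = field(
        default_factory=lambda: {"boreal": 0.431, "temperate": 0.569}
    )
    partial_share_by_biome: Mapping[str, float] = field(
        default_factory=lambda: {"boreal": 0.103, "temperate": 0.206}
    )
    pool_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "live_trees": 0.254,
            "forest_floor": 0.201,
            "coarse_woody_debris": 0.192,
            "snags": 0.153,
            "mineral_soil": 0.114,
            "understory": 0.087,
        }
    )
    #: lognormal time draws: (median, sigma, max) per treatment
    time_distribution: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "clearcut": (15.0, 1.21, 110.0),
            "partial": (9.0, 0.55, 50.0),
        }
    )
    #: fraction of studies that inventory a full pool suite on each unit —
    #: the source of composable total-ecosystem-carbon observations
    inventory_study_rate: float = 0.2
    inventory_pools: tuple[str, ...] = (
        "live_trees",
        "mineral_soil",
        "coarse_woody_debris",
    )
    #: set X̄_T = 0 on clearcut live-tree rows younger than this (years);
    #: exercises downstream handling of −100% observations.  0 disables.
    zero_mean_before: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not 0 <= self.missing_variance_rate <= 1:
            raise ValueError("missing_variance_rate must lie in [0, 1]")
        if self.n_studies <= 0:
            raise ValueError("n_studies must be positive")
        for key in self.time_model:
            pool, treatment = key
            covered = any(k[0] == pool and k[1] == treatment for k in self.true_effects)
            if not covered:
                raise ValueError(
                    f"time_model stratum {key} has no entry in true_effects"
                )

    def theta(self, pool: str, treatment: str, biome: str, t: float) -> float:
        """Effective true log response ratio for a stratum at time t."""
        traj = self.time_model.get((pool, treatment))
        if traj is not None:
            return float(traj(t))
        return float(self.true_effects.get((pool, treatment, biome), 0.0))


def default_config(seed: int = 0) -> SyntheticConfig:
    """Configuration emulating the compiled field database.

    Stratum effects, composition shares, time distributions and reference
    stocks follow the compiled literature's headline values; see the methods
    note for the calibration of each trajectory.
    """
    effects: dict[tuple[str, str, str], float] = {}
    for biome in BIOMES:
        # live trees: time-varying (trajectories below); entries anchor validation
        effects[("live_trees", "clearcut", biome)] = math.log(0.22)
        effects[("live_trees", "partial", biome)] = math.log(0.55)
        effects[("snags", "clearcut", biome)] = -1.0
        effects[("snags", "partial", biome)] = -0.35
        effects[("understory", "clearcut", biome)] = math.log(2.21)
        effects[("understory", "partial", biome)] = math.log(2.21)
        effects[("coarse_woody_debris", "clearcut", biome)] = 0.0
        effects[("coarse_woody_debris", "partial", biome)] = 0.0
        effects[("mineral_soil", "clearcut", biome)] = 0.0
        effects[("mineral_soil", "partial", biome)] = 0.0
    effects[("forest_floor", "clearcut", "temperate")] = math.log(0.79)
    effects[("forest_floor", "partial", "temperate")] = -0.08
    effects[("forest_floor", "clearcut", "boreal")] = 0.0
    effects[("forest_floor", "partial", "boreal")] = 0.0

    # clearcut live trees: −99.6% at t=0, passing the partial-cut line near
    # t≈30 y and approaching the reference by t≈60 y
    cc_live = Trajectory("saturating", (-5.41, 12.8))
    # partial-cut live trees: −50% at t=0 rising linearly to −25% at t=50
    pc_live = linear_from_percents(-50.0, -25.0, 50.0)
    time_model = {
        ("live_trees", "clearcut"): cc_live,
        ("live_trees", "partial"): pc_live,
        # deadwood pulse: +136%/+43% just after harvest, trough −68% at ~25 y
        ("coarse_woody_debris", "clearcut"): Trajectory(
            "u_shaped", (math.log(2.36), math.log(0.32), 25.0)
        ),
        ("coarse_woody_debris", "partial"): Trajectory(
            "u_shaped", (math.log(1.43), math.log(0.32), 25.0)
        ),
    }
    # reference stocks per pool: shares of a 223.9 Mg C ha⁻¹ ecosystem total,
    # spread ±40% around each pool's mean contribution
    pool_means = {
        "live_trees": 0.409,
        "mineral_soil": 0.336,
        "forest_floor": 0.1424,
        "snags": 0.0576,
        "coarse_woody_debris": 0.0474,
        "understory": 0.0072,
    }
    control_ranges = {
        pool: (0.6 * share * 223.9, 1.4 * share * 223.9)
        for pool, share in pool_means.items()
    }
    return SyntheticConfig(
        true_effects=effects,
        time_model=time_model,
        control_mean_range=control_ranges,
        zero_mean_before=1.0,
        seed=seed,
    )


@dataclass
class GenerativeTruth:
    """What the generator actually drew — the target of recovery tests."""

    config: SyntheticConfig
    study_effects: pd.DataFrame  # study_id, biome, b (N(0, tau^2) draw), inventory flag
    theta_table: pd.DataFrame  # per-row effective theta and components

    def to_csv(self, path) -> None:
        self.theta_table.to_csv(path, index=False)


def _draw_time(rng: np.random.Generator, treatment: str, cfg: SyntheticConfig) -> float:
    median, sigma, t_max = cfg.time_distribution[treatment]
    while True:
        t = float(rng.lognormal(mean=math.log(median), sigma=sigma))
        if t <= t_max:
            return round(t, 1)


def generate_dataset(cfg: SyntheticConfig) -> tuple[Dataset, GenerativeTruth]:
    """Draw a synthetic database plus its generative truth.

    Deterministic: identical config (including ``seed``) gives identical
    output, byte-for-byte after :func:`~harvestmeta.data_model.write_dataset`.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pools = [p for p in POOLS if cfg.pool_shares.get(p, 0) > 0]
    pool_p = np.array([cfg.pool_shares[p] for p in pools])
    pool_p = pool_p / pool_p.sum()
    biome_p = np.array([cfg.biome_shares.get(b, 0.0) for b in BIOMES])
    biome_p = biome_p / biome_p.sum()
    default_range = (20.0, 80.0)

    rows = []
    truth_rows = []
    study_rows = []

    def make_row(
        study_id: str, unit_id: str, pool: str, treatment: str, biome: str,
        t: float, b_s: float,
    ) -> None:
        theta_t = cfg.theta(pool, treatment, biome, t)
        theta_s = theta_t + b_s
        c_lo, c_hi = cfg.control_mean_range.get(pool, default_range)
        mu_c = float(rng.uniform(c_lo, c_hi))
        mu_t = mu_c * math.exp(theta_s)
        n_t = int(rng.integers(cfg.n_reps_range[0], cfg.n_reps_range[1] + 1))
        n_c = int(rng.integers(cfg.n_reps_range[0], cfg.n_reps_range[1] + 1))
        if cfg.cv_within > 0:
            sd_t, sd_c = cfg.cv_within * mu_t, cfg.cv_within * mu_c
            mean_t = max(0.0, float(rng.normal(mu_t, sd_t / math.sqrt(n_t))))
            mean_c = float(rng.normal(mu_c, sd_c / math.sqrt(n_c)))
            while mean_c <= 0:
                mean_c = float(rng.normal(mu_c, sd_c / math.sqrt(n_c)))
            se_t, se_c = sd_t / math.sqrt(n_t), sd_c / math.sqrt(n_c)
        else:
            mean_t, mean_c = mu_t, mu_c
            se_t = se_c = 0.0
        zeroed = (
            cfg.zero_mean_before > 0
            and pool == "live_trees"
            and treatment == "clearcut"
            and t < cfg.zero_mean_before
        )
        if zeroed:
            mean_t, se_t = 0.0, 0.0
        missing = rng.random() < cfg.missing_variance_rate
        rows.append(
            {
                "study_id": study_id,
                "unit_id": unit_id,
                "pool": pool,
                "treatment": treatment,
                "biome": biome,
                "reference_type": "old_forest"
                if treatment == "clearcut"
                else ("unmanaged_80plus" if biome == "boreal" else "old_forest"),
                "time_since_treatment": t,
                "mean_treatment": mean_t,
                "mean_control": mean_c,
                "se_treatment": None if missing else se_t,
                "se_control": None if missing else se_c,
                "n_treatment": None if missing else n_t,
                "n_control": None if missing else n_c,
                "sampling_depth": float(rng.integers(7, 151))
                if pool == "mineral_soil"
                else None,
            }
        )
        truth_rows.append(
            {
                "study_id": study_id,
                "unit_id": unit_id,
                "pool": pool,
                "treatment": treatment,
                "biome": biome,
                "time_since_treatment": t,
                "theta_time": theta_t,
                "study_effect": b_s,
                "theta_effective": theta_s,
                "variance_missing": missing,
                "zeroed": zeroed,
            }
        )

    for s in range(cfg.n_studies):
        study_id = f"S{s + 1:03d}"
        biome = BIOMES[rng.choice(len(BIOMES), p=biome_p)]
        p_partial = cfg.partial_share_by_biome.get(biome, 0.15)
        b_s = rng.normal(0.0, cfg.tau) if cfg.tau > 0 else 0.0
        lo, hi = cfg.obs_per_study
        n_obs = int(rng.integers(lo, hi + 1))
        inventory = (
            len(cfg.inventory_pools) > 0
            and rng.random() < cfg.inventory_study_rate
        )
        study_rows.append(
            {
                "study_id": study_id,
                "biome": biome,
                "b": b_s,
                "inventory": inventory,
            }
        )
        if inventory:
            # inventory design: each unit-occasion measures a full pool suite
            # at one shared time, so a total-carbon observation can be composed
            n_occasions = max(1, round(n_obs / len(cfg.inventory_pools)))
            for o in range(n_occasions):
                unit_id = f"{study_id}-u{o + 1}"
                treatment = "partial" if rng.random() < p_partial else "clearcut"
                t = _draw_time(rng, treatment, cfg)
                for pool in cfg.inventory_pools:
                    make_row(study_id, unit_id, pool, treatment, biome, t, b_s)
        else:
            # survey design: treatment fixed per unit, pools drawn by share
            n_units = max(1, int(math.ceil(n_obs / 2)))
            unit_treatment = [
                "partial" if rng.random() < p_partial else "clearcut"
                for _ in range(n_units)
            ]
            for j in range(n_obs):
                u = j % n_units
                unit_id = f"{study_id}-u{u + 1}"
                treatment = unit_treatment[u]
                pool = pools[rng.choice(len(pools), p=pool_p)]
                t = _draw_time(rng, treatment, cfg)
                make_row(study_id, unit_id, pool, treatment, biome, t, b_s)

    df = pd.DataFrame(rows)
    # de-duplicate the (study, unit, pool, treatment, time) key: a unit is
    # measured once per pool per occasion, so collisions get a fresh unit
    key = ["study_id", "unit_id", "pool", "treatment", "time_since_treatment"]
    dup = df.duplicated(subset=key, keep="first")
    while dup.any():
        df.loc[dup, "unit_id"] = df.loc[dup, "unit_id"] + "x"
        dup = df.duplicated(subset=key, keep="first")
    truth = GenerativeTruth(
        config=cfg,
        study_effects=pd.DataFrame(study_rows),
        theta_table=pd.DataFrame(truth_rows),
    )
    return Dataset(df=df, provenance=f"synthetic seed={cfg.seed}"), truth


def config_to_yaml(cfg: SyntheticConfig, path) -> None:
    """Serialise a config (trajectories as shape/params pairs) to YAML."""
    d = {
        "n_studies": cfg.n_studies,
        "obs_per_study": list(cfg.obs_per_study),
        "tau": cfg.tau,
        "cv_within": cfg.cv_within,
        "n_reps_range": list(cfg.n_reps_range),
        "missing_variance_rate": cfg.missing_variance_rate,
        "zero_mean_before": cfg.zero_mean_before,
        "seed": cfg.seed,
        "true_effects": {
            "|".join(k): float(v) for k, v in cfg.true_effects.items()
        },
        "time_model": {
            "|".join(k): {"shape": tr.shape, "params": list(tr.params)}
            for k, tr in cfg.time_model.items()
        },
        "control_mean_range": {k: list(v) for k, v in cfg.control_mean_range.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def config_from_yaml(path, seed: int | None = None) -> SyntheticConfig:
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    cfg = default_config()
    kwargs = {}
    for k in (
        "n_studies",
        "tau",
        "cv_within",
        "missing_variance_rate",
        "zero_mean_before",
        "seed",
    ):
        if k in d:
            kwargs[k] = d[k]
    if "obs_per_study" in d:
        kwargs["obs_per_study"] = tuple(d["obs_per_study"])
    if "n_reps_range" in d:
        kwargs["n_reps_range"] = tuple(d["n_reps_range"])
    if "true_effects" in d:
        kwargs["true_effects"] = {
            tuple(k.split("|")): float(v) for k, v in d["true_effects"].items()
        }
    if "time_model" in d:
        kwargs["time_model"] = {
            tuple(k.split("|")): Trajectory(v["shape"], tuple(v["params"]))
            for k, v in d["time_model"].items()
        }
    if "control_mean_range" in d:
        kwargs["control_mean_range"] = {
            k: tuple(v) for k, v in d["control_mean_range"].items()
        }
    cfg = replace(cfg, **kwargs)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg
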