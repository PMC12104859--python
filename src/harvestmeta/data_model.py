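"""Observation-level data model and CSV I/O for the harvest carbon database.

One row of the database is a single treatment/control comparison: the mean
carbon stock (Mg C ha⁻¹) of one pool, in one experimental unit of one study,
at one time since the most recent cut, paired with the stock of an uncut
reference stand.  Optional columns carry the sampling uncertainty (SE or SD
plus replicate counts) needed for inverse-variance weighting; roughly one in
five published observations lacks them, and the analysis runs a parallel
unweighted track for exactly that reason.

Validation distinguishes *hard* invariants (a violated row cannot enter any
analysis: non-positive reference stock, unknown category level, variance
info for one arm only, duplicate key) from *soft* ones that are merely
flagged (mineral-soil sampling depth outside the observed 7–150 cm range,
time since treatment beyond the 110-year horizon).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "POOLS",
    "TREATMENTS",
    "BIOMES",
    "REFERENCE_TYPES",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "DEFAULT_TIME_BINS",
    "CarbonObservation",
    "Dataset",
    "DatasetSummary",
    "SchemaError",
    "ValidationError",
    "ValidationIssue",
    "assign_time_class",
    "load_column_map",
    "read_dataset",
    "summarize_dataset",
    "validate_table",
    "write_dataset",
]

POOLS = (
    "live_trees",
    "snags",
    "understory",
    "coarse_woody_debris",
    "forest_floor",
    "mineral_soil",
)
TREATMENTS = ("clearcut", "partial")
BIOMES = ("boreal", "temperate")
REFERENCE_TYPES = ("old_forest", "unmanaged_80plus")

#: columns every input file must provide (after column-mapping)
REQUIRED_COLUMNS = (
    "study_id",
    "pool",
    "treatment",
    "biome",
    "reference_type",
    "time_since_treatment",
    "mean_treatment",
    "mean_control",
)
#: columns that may be absent or empty
OPTIONAL_COLUMNS = (
    "unit_id",
    "se_treatment",
    "se_control",
    "n_treatment",
    "n_control",
    "sampling_depth",
)
ALL_COLUMNS = REQUIRED_COLUMNS[:1] + ("unit_id",) + REQUIRED_COLUMNS[1:] + OPTIONAL_COLUMNS[1:]

KEY_COLUMNS = ("study_id", "unit_id", "pool", "treatment", "time_since_treatment")

SAMPLING_DEPTH_RANGE = (7.0, 150.0)
MAX_EXPECTED_TIME = 110.0

#: decade bins used whenever continuous time is grouped into classes
DEFAULT_TIME_BINS = tuple(float(e) for e in range(0, 130, 10))

_CATEGORY_LEVELS = {
    "pool": POOLS,
    "treatment": TREATMENTS,
    "biome": BIOMES,
    "reference_type": REFERENCE_TYPES,
}

_FLOAT_COLUMNS = (
    "time_since_treatment",
    "mean_treatment",
    "mean_control",
    "se_treatment",
    "se_control",
    "sampling_depth",
)
_INT_COLUMNS = ("n_treatment", "n_control")


class SchemaError(ValueError):
    """The input table is structurally unusable (e.g. a required column is missing)."""


class ValidationError(ValueError):
    """One or more rows violate a hard invariant of the data model."""

    def __init__(self, issues: Sequence["ValidationIssue"]):
        self.issues = list(issues)
        lines = [str(i) for i in self.issues[:20]]
        if len(self.issues) > 20:
            lines.append(f"... and {len(self.issues) - 20} more")
        super().__init__("row validation failed:\n" + "\n".join(lines))


@dataclass(frozen=True)
class ValidationIssue:
    """A row-indexed diagnostic produced during validation."""

    row: int
    column: str
    message: str
    level: str = "error"  # "error" rejects the row, "warning" does not

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row} [{self.level}] {self.column}: {self.message}"


@dataclass(frozen=True)
class CarbonObservation:
    """One treatment/control carbon comparison for one pool at one time point."""

    study_id: str
    unit_id: str
    pool: str
    treatment: str
    biome: str
    reference_type: str
    time_since_treatment: float
    mean_treatment: float
    mean_control: float
    se_treatment: float | None = None
    se_control: float | None = None
    n_treatment: int | None = None
    n_control: int | None = None
    sampling_depth: float | None = None

    @property
    def has_variance_info(self) -> bool:
        return self.se_treatment is not None and self.se_control is not None


@dataclass
class Dataset:
    """A validated collection of :class:`CarbonObservation` rows.

    Internally backed by a ``pandas.DataFrame`` in canonical column order;
    ``observations`` materialises the dataclass view on demand.
    """

    df: pd.DataFrame
    provenance: str = ""
    issues: list[ValidationIssue] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.df = _coerce_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def observations(self) -> list[CarbonObservation]:
        out = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            for c in ("se_treatment", "se_control", "sampling_depth"):
                d[c] = None if pd.isna(d[c]) else float(d[c])
            for c in _INT_COLUMNS:
                d[c] = None if pd.isna(d[c]) else int(d[c])
            d["time_since_treatment"] = float(d["time_since_treatment"])
            d["mean_treatment"] = float(d["mean_treatment"])
            d["mean_control"] = float(d["mean_control"])
            out.append(CarbonObservation(**d))
        return out

    @classmethod
    def from_observations(
        cls, obs: Iterable[CarbonObservation], provenance: str = ""
    ) -> "Dataset":
        rows = [dataclasses.asdict(o) for o in obs]
        df = pd.DataFrame(rows, columns=list(ALL_COLUMNS))
        return cls(df=df, provenance=provenance)

    def equals(self, other: "Dataset") -> bool:
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        return a.equals(b)


def _coerce_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Put a raw frame into canonical column order and dtypes."""
    df = df.copy()
    for col in ALL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[list(ALL_COLUMNS)]
    for col in ("study_id", "unit_id"):
        df[col] = df[col].astype("string")
    for col in _CATEGORY_LEVELS:
        df[col] = df[col].astype("string")
    for col in _FLOAT_COLUMNS:
        # exact strtod parsing: pandas' fast float parser can be 1 ulp off,
        # which would break the read/write round-trip contract
        df[col] = df[col].map(_parse_float).astype(float)
    for col in _INT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df.reset_index(drop=True)


def _parse_float(v) -> float:
    if v is None or v is pd.NA:
        return float("nan")
    if isinstance(v, str):
        v = v.strip()
        if not v:
            return float("nan")
        try:
            return float(v)
        except ValueError:
            return float("nan")
    try:
        return float(v)
    except (TypeError, ValueError):
        return float("nan")


def load_column_map(path: str | Path) -> dict[str, str]:
    """Read a YAML column-mapping config: canonical field -> source column."""
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, Mapping):
        raise SchemaError("column map must be a mapping of canonical -> source column")
    unknown = set(mapping) - set(ALL_COLUMNS)
    if unknown:
        raise SchemaError(f"column map refers to unknown canonical fields: {sorted(unknown)}")
    return {str(k): str(v) for k, v in mapping.items()}


def validate_table(df: pd.DataFrame) -> tuple[pd.DataFrame, list[ValidationIssue]]:
    """Validate a coerced table; return (clean rows, all diagnostics).

    Every malformed row yields at least one diagnostic — rows are never
    silently dropped.  Returned frame keeps only rows free of hard errors.
    """
    issues: list[ValidationIssue] = []
    bad = np.zeros(len(df), dtype=bool)

    def flag(mask: np.ndarray, column: str, message, level: str = "error") -> None:
        nonlocal bad
        for i in np.flatnonzero(np.asarray(mask)):
            msg = message(df.iloc[i]) if callable(message) else message
            issues.append(ValidationIssue(int(i), column, msg, level))
        if level == "error":
            bad |= np.asarray(mask)

    flag(df["study_id"].isna().to_numpy(), "study_id", "study_id is required")
    for col, levels in _CATEGORY_LEVELS.items():
        m = ~df[col].isin(levels) | df[col].isna()
        flag(
            m.to_numpy(),
            col,
            lambda r, c=col, lv=levels: f"unknown level {r[c]!r}; allowed: {list(lv)}",
        )

    mc = df["mean_control"].to_numpy()
    flag(
        ~(mc > 0),
        "mean_control",
        "mean_control must be > 0 (log response ratio denominator)",
    )
    mt = df["mean_treatment"].to_numpy()
    flag(~(mt >= 0) | np.isnan(mt), "mean_treatment", "mean_treatment must be >= 0")
    t = df["time_since_treatment"].to_numpy()
    flag(~(t >= 0) | np.isnan(t), "time_since_treatment", "time since treatment must be >= 0")
    flag(
        (t > MAX_EXPECTED_TIME) & ~np.isnan(t),
        "time_since_treatment",
        f"time since treatment exceeds the {MAX_EXPECTED_TIME:.0f}-year observed horizon",
        level="warning",
    )

    # variance info travels together within an arm: se present <=> n present
    for arm in ("treatment", "control"):
        se_na = df[f"se_{arm}"].isna().to_numpy()
        n_na = df[f"n_{arm}"].isna().to_numpy()
        flag(
            se_na != n_na,
            f"se_{arm}",
            f"se_{arm} and n_{arm} must both be present or both absent",
        )
        se = df[f"se_{arm}"].to_numpy()
        flag((se < 0) & ~se_na, f"se_{arm}", "standard errors must be >= 0")
        n = df[f"n_{arm}"].to_numpy(dtype=float, na_value=np.nan)
        flag((n <= 0) & ~n_na, f"n_{arm}", "replicate counts must be positive")

    depth = df["sampling_depth"].to_numpy()
    has_depth = ~np.isnan(depth)
    lo, hi = SAMPLING_DEPTH_RANGE
    flag(
        has_depth & ((depth < lo) | (depth > hi)),
        "sampling_depth",
        f"sampling depth outside the observed {lo:.0f}-{hi:.0f} cm range",
        level="warning",
    )
    flag(
        has_depth & (df["pool"] != "mineral_soil").to_numpy(),
        "sampling_depth",
        "sampling depth is only meaningful for mineral_soil rows",
        level="warning",
    )

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep="first").to_numpy()
    flag(
        dup,
        "study_id",
        "duplicate (study_id, unit_id, pool, treatment, time_since_treatment) key",
    )

    return df.loc[~bad].reset_index(drop=True), issues


def read_dataset(
    path: str | Path | io.IOBase,
    column_map: Mapping[str, str] | str | Path | None = None,
    dispersion: str = "se",
    strict: bool = True,
    provenance: str | None = None,
) -> Dataset:
    """Read and validate a carbon-observation CSV.

    Parameters
    ----------
    path
        CSV file (comma-separated, UTF-8, ``.`` decimal, empty cell = missing).
    column_map
        Optional mapping from canonical field names to the file's column
        names, or the path of a YAML file holding one.  Used to load
        externally deposited tables without renaming columns by hand.
    dispersion
        ``"se"`` if the file's dispersion columns are standard errors
        (default), ``"sd"`` if they are standard deviations — then converted
        to SEs as SD/sqrt(n) at load.
    strict
        If True (default) any hard-invariant violation raises
        :class:`ValidationError`.  If False offending rows are dropped and
        the diagnostics are kept on ``Dataset.issues``.
    """
    if dispersion not in ("se", "sd"):
        raise ValueError("dispersion must be 'se' or 'sd'")
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    if isinstance(column_map, (str, Path)):
        column_map = load_column_map(column_map)
    if column_map:
        missing_src = [src for src in column_map.values() if src not in raw.columns]
        if missing_src:
            raise SchemaError(f"mapped source columns not in file: {missing_src}")
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    df = _coerce_frame(raw)
    if dispersion == "sd":
        for arm in ("treatment", "control"):
            n = df[f"n_{arm}"].astype(float)
            df[f"se_{arm}"] = df[f"se_{arm}"] / np.sqrt(n)

    # synthesize unit ids where absent: study_id + row ordinal
    na_unit = df["unit_id"].isna()
    if na_unit.any():
        ordinals = df.groupby("study_id").cumcount().astype(str)
        df.loc[na_unit, "unit_id"] = df.loc[na_unit, "study_id"] + "-u" + ordinals[na_unit]

    clean, issues = validate_table(df)
    hard = [i for i in issues if i.level == "error"]
    if strict and hard:
        raise ValidationError(hard)
    prov = provenance if provenance is not None else str(path)
    return Dataset(df=clean, provenance=prov, issues=issues)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a Dataset as CSV; ``read_dataset`` round-trips it field-for-field.

    Output is byte-stable: fixed column order, ``repr`` float formatting,
    empty cells for missing values, ``\\n`` line endings.
    """
    df = ds.df.copy()
    for col in _INT_COLUMNS:
        df[col] = df[col].astype(object)
    # shortest-roundtrip float formatting so read(write(ds)) is exact
    df.to_csv(
        path,
        index=False,
        lineterminator="\n",
        float_format=lambda v: repr(float(v)),
    )


def issues_frame(issues: Sequence[ValidationIssue]) -> pd.DataFrame:
    """Machine-readable validation report (one row per diagnostic)."""
    return pd.DataFrame(
        [(i.row, i.level, i.column, i.message) for i in issues],
        columns=["row", "level", "column", "message"],
    )


def assign_time_class(
    times: Iterable[float], edges: Sequence[float] = DEFAULT_TIME_BINS
) -> pd.Series:
    """Bin continuous time-since-treatment into labelled classes.

    Bins are left-closed ``[e_i, e_{i+1})``; times at or beyond the last edge
    fall into an open-ended top class.
    """
    index = times.index if isinstance(times, pd.Series) else None
    t = pd.Series(np.asarray(list(times), dtype=float), index=index)
    edges = list(edges)
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    top = f"[{edges[-1]:g},inf)"
    idx = np.searchsorted(edges, t.to_numpy(), side="right") - 1
    out = []
    for i, v in zip(idx, t.to_numpy()):
        if np.isnan(v) or v < edges[0]:
            out.append(None)
        elif i >= len(labels):
            out.append(top)
        else:
            out.append(labels[i])
    return pd.Series(out, dtype="string", index=index)


@dataclass
class DatasetSummary:
    """Composition of a dataset: stratum shares, time quartiles, variance completeness."""

    n_observations: int
    n_studies: int
    biome: pd.DataFrame
    treatment: pd.DataFrame
    pool: pd.DataFrame
    time_by_treatment: pd.DataFrame
    variance_complete_fraction: float

    @property
    def empty(self) -> bool:
        return self.n_observations == 0


def _composition(s: pd.Series) -> pd.DataFrame:
    counts = s.value_counts()
    return pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / counts.sum()}
    ).rename_axis(s.name)


def summarize_dataset(ds: Dataset) -> DatasetSummary:
    """Per-stratum counts/percentages, time quartiles per treatment, and the
    fraction of rows carrying complete variance information."""
    df = ds.df
    if len(df) == 0:
        empty = pd.DataFrame(columns=["count", "percent"])
        return DatasetSummary(0, 0, empty, empty, empty, pd.DataFrame(), float("nan"))
    time_rows = []
    for tr, sub in df.groupby("treatment", observed=True):
        t = sub["time_since_treatment"]
        time_rows.append(
            {
                "treatment": tr,
                "n": len(sub),
                "q25": t.quantile(0.25),
                "median": t.median(),
                "q75": t.quantile(0.75),
                "max": t.max(),
            }
        )
    complete = (~df["se_treatment"].isna() & ~df["se_control"].isna()).mean()
    return DatasetSummary(
        n_observations=len(df),
        n_studies=df["study_id"].nunique(),
        biome=_composition(df["biome"]),
        treatment=_composition(df["treatment"]),
        pool=_composition(df["pool"]),
        time_by_treatment=pd.DataFrame(time_rows).set_index("treatment"),
        variance_complete_fraction=float(complete),
    )
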