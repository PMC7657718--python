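"""Long-format touchpoint logs and the raw-to-wide journey transformation.

A *touchpoint* is one recorded interaction of a user with a digital
intervention at a point in time: a self-reported value (diary entry,
questionnaire item) or a system event (login, automated email, trigger).
This module ingests long-format logs (one row per user x timestamp x
variable), bins touchpoints into time windows, aggregates within windows
into a wide journey table, carries questionnaire values forward, and
collapses each user's journey into a single feature row for supervised
learning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("user_id", "timestamp", "variable", "value", "source")

#: value_type labels
NUMERIC = "numeric"
CATEGORICAL = "categorical"
EVENT = "event"

WITHIN_WINDOW_AGGS = ("mean", "mode", "sum", "last", "max", "min")
USER_AGGS = ("mean", "mode", "sum", "last")


@dataclass(frozen=True)
class VariableSpec:
    """How one variable is typed and aggregated along the pipeline.

    Parameters
    ----------
    name : str
        Variable name as it appears in the long-format log.
    value_type : {"numeric", "categorical", "event"}
    within_window_agg : {"mean", "mode", "sum", "last", "max", "min"}
        Collapses multiple touchpoints of this variable inside one time
        window to a single cell.
    user_agg : {"mean", "mode", "sum", "last"}
        Collapses a user's per-window values to one number for the
        user-level feature table.
    carry_forward : bool
        Fill missing windows with the last observed value (LOCF), the
        treatment given to questionnaires administered before each core.
    protected : bool
        Exempt from missingness-threshold deletion (used for the
        theory-driven feature catalog).
    """

    name: str
    value_type: str
    within_window_agg: str = "mean"
    user_agg: str = "mean"
    carry_forward: bool = False
    protected: bool = False

    def __post_init__(self) -> None:
        if self.value_type not in (NUMERIC, CATEGORICAL, EVENT):
            raise ValueError(f"unknown value_type {self.value_type!r} for {self.name!r}")
        for agg, allowed in ((self.within_window_agg, WITHIN_WINDOW_AGGS), (self.user_agg, USER_AGGS)):
            if agg not in allowed:
                raise ValueError(f"unknown aggregation {agg!r} for {self.name!r}")
        if self.within_window_agg == "mode" and self.value_type != CATEGORICAL:
            raise ValueError(f"mode aggregation requires a categorical variable ({self.name!r})")
        if self.user_agg == "mode" and self.value_type != CATEGORICAL:
            raise ValueError(f"mode aggregation requires a categorical variable ({self.name!r})")
        if self.within_window_agg == "sum" and self.value_type == CATEGORICAL:
            raise ValueError(f"sum aggregation requires numeric or event values ({self.name!r})")
        if self.user_agg == "sum" and self.value_type == CATEGORICAL:
            raise ValueError(f"sum aggregation requires numeric or event values ({self.name!r})")


def load_variable_specs(path) -> dict[str, VariableSpec]:
    """Read a YAML/JSON variable-spec file: a list of mappings mirroring
    :class:`VariableSpec` fields (``name`` and ``value_type`` required)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    specs = {}
    for entry in raw:
        spec = VariableSpec(**entry)
        specs[spec.name] = spec
    return specs


def default_spec(name: str, value_type: str) -> VariableSpec:
    """Default aggregation: numeric -> mean, categorical -> mode, event -> sum."""
    if value_type == NUMERIC:
        return VariableSpec(name, NUMERIC, "mean", "mean")
    if value_type == CATEGORICAL:
        return VariableSpec(name, CATEGORICAL, "mode", "mode")
    return VariableSpec(name, EVENT, "sum", "sum")


@dataclass
class TouchPointLog:
    """A validated, time-sorted long-format log.

    ``data`` has columns ``user_id, timestamp, variable, value, source``
    plus ``numeric_value`` (float, NaN for categoricals) and, after
    :func:`assign_windows`, ``window_index``.  ``value_types`` maps each
    variable to its inferred type; events carry implicit value 1.
    """

    data: pd.DataFrame
    value_types: dict[str, str] = field(default_factory=dict)
    window_days: int | None = None
    origin: str | None = None
    origins: pd.Series | None = None  # per-user origin date when windows assigned

    @property
    def users(self) -> np.ndarray:
        return self.data["user_id"].unique()

    def __len__(self) -> int:
        return len(self.data)

    def filter(self, mask: pd.Series) -> "TouchPointLog":
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    def restrict_to_dates(self, cutoff: Mapping) -> "TouchPointLog":
        """Keep only users present in ``cutoff`` and their touchpoints on or
        before that user's cutoff date (used for per-core analyses)."""
        cut = pd.Series(cutoff)
        d = self.data[self.data["user_id"].isin(cut.index)]
        keep = d["timestamp"].dt.normalize() <= d["user_id"].map(cut)
        return replace(self, data=d.loc[keep].reset_index(drop=True))

    def to_csv(self, path) -> None:
        out = self.data[list(REQUIRED_COLUMNS)].copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, index=False)


def _infer_value_type(values: pd.Series, name: str) -> tuple[str, pd.Series]:
    """Classify a variable from its raw string values.

    All-empty -> event (implicit value 1); all numeric-parseable ->
    numeric; none parseable -> categorical; a mix of numeric and
    non-numeric values is a hard error naming the variable.
    """
    observed = values[values.notna() & (values.astype(str).str.strip() != "")]
    if observed.empty:
        return EVENT, pd.Series(1.0, index=values.index)
    as_num = pd.to_numeric(observed, errors="coerce")
    n_num = int(as_num.notna().sum())
    if n_num == len(observed):
        full = pd.Series(np.nan, index=values.index, dtype=float)
        full.loc[observed.index] = as_num.astype(float)
        return NUMERIC, full
    if n_num == 0:
        return CATEGORICAL, pd.Series(np.nan, index=values.index, dtype=float)
    raise ValueError(
        f"variable {name!r} mixes numeric and categorical values "
        f"({n_num} numeric of {len(observed)} observed)"
    )


def parse_touchpoints(source, value_types: Mapping[str, str] | None = None) -> TouchPointLog:
    """Read and validate a long-format touchpoint log.

    ``source`` is a CSV path/buffer with header
    ``user_id,timestamp,variable,value,source`` (ISO-8601 timestamps) or an
    equivalent DataFrame.  Rows with unparseable timestamps are rejected
    with a logged warning.  A variable whose values mix numeric and
    categorical entries raises ``ValueError``.  ``value_types`` may force
    the type of specific variables (e.g. numeric-coded categories).
    """
    if isinstance(source, pd.DataFrame):
        df = source.reset_index(drop=True).copy()
    else:
        df = pd.read_csv(source, dtype={"value": str}, keep_default_na=False, na_values=[""])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"log is missing required columns: {missing}")
    df = df[list(REQUIRED_COLUMNS)].copy()

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    bad = ts.isna()
    if bad.any():
        logger.warning("rejected %d touchpoint row(s) with unparseable timestamps", int(bad.sum()))
        df = df.loc[~bad]
        ts = ts.loc[~bad]
    df["timestamp"] = ts

    types: dict[str, str] = {}
    numeric_col = pd.Series(np.nan, index=df.index, dtype=float)
    for name, grp in df.groupby("variable", sort=True):
        if value_types and name in value_types:
            vt = value_types[name]
            if vt == EVENT:
                numeric_col.loc[grp.index] = 1.0
            elif vt == NUMERIC:
                numeric_col.loc[grp.index] = pd.to_numeric(grp["value"], errors="coerce")
        else:
            vt, nums = _infer_value_type(grp["value"], str(name))
            numeric_col.loc[grp.index] = nums
        types[str(name)] = vt
    df["numeric_value"] = numeric_col

    df = df.sort_values(["user_id", "timestamp", "variable"], kind="stable").reset_index(drop=True)
    return TouchPointLog(data=df, value_types=types)


def assign_windows(
    log: TouchPointLog,
    window_days: int = 1,
    origin: str = "per_user_first",
    origin_date=None,
) -> TouchPointLog:
    """Tag every touchpoint with a window index.

    Windows are half-open ``[origin + i*w, origin + (i+1)*w)`` in whole
    days; timestamps are binned by calendar date, so with ``w=7`` a
    touchpoint exactly 7 days after the origin falls in window 1.  The
    origin is each user's first touchpoint date (default) or a fixed date.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    d = log.data.copy()
    dates = d["timestamp"].dt.normalize()
    if origin == "per_user_first":
        origins = dates.groupby(d["user_id"]).transform("min")
        origin_by_user = dates.groupby(d["user_id"]).min()
    elif origin == "fixed_date":
        if origin_date is None:
            raise ValueError("fixed_date origin requires origin_date")
        o = pd.Timestamp(origin_date).normalize()
        if (dates < o).any():
            raise ValueError("touchpoint before the fixed origin date")
        origins = pd.Series(o, index=d.index)
        origin_by_user = pd.Series(o, index=pd.Index(d["user_id"].unique(), name="user_id"))
    else:
        raise ValueError(f"unknown origin policy {origin!r}")
    d["window_index"] = ((dates - origins).dt.days // window_days).astype(int)
    return replace(
        log, data=d, window_days=window_days, origin=origin, origins=origin_by_user
    )


def _mode_earliest(values: Iterable) -> object:
    """Most frequent value; ties broken by earliest observation."""
    counts: dict = {}
    for v in values:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        counts[v] = counts.get(v, 0) + 1
    if not counts:
        return np.nan
    # dicts preserve insertion order, and max() returns the first maximum,
    # so ties resolve to the earliest-observed value.
    return max(counts, key=counts.get)


@dataclass
class JourneyTable:
    """Wide journey matrix: one row per (user, window), one column per feature.

    ``data`` is indexed by a (user_id, window_index) MultiIndex with
    explicit NaN for missing cells.  Only (user, window) pairs holding at
    least one touchpoint are materialised; :meth:`to_dense_grid` expands to
    the full 0..max grid per user.
    """

    data: pd.DataFrame
    window_days: int
    origin: str
    value_types: dict[str, str]
    specs: dict[str, VariableSpec]
    origins: pd.Series | None = None

    @property
    def users(self) -> np.ndarray:
        return self.data.index.get_level_values("user_id").unique().to_numpy()

    def columns_of_type(self, value_type: str) -> list[str]:
        return [c for c in self.data.columns if self.value_types.get(c) == value_type]

    def to_dense_grid(self) -> "JourneyTable":
        parts = []
        for uid, grp in self.data.groupby(level="user_id", sort=False):
            hi = grp.index.get_level_values("window_index").max()
            idx = pd.MultiIndex.from_product([[uid], range(int(hi) + 1)], names=["user_id", "window_index"])
            parts.append(grp.reindex(idx))
        return replace(self, data=pd.concat(parts))

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


def aggregate_within_window(
    log: TouchPointLog, specs: Mapping[str, VariableSpec] | None = None
) -> JourneyTable:
    """Collapse touchpoints to one cell per (user, window, variable).

    Defaults follow the diary convention: mean for numeric, mode for
    categorical (ties to the earliest-observed level) and sum for events.
    Windows with no touchpoint for a variable stay missing.
    """
    if log.window_days is None or "window_index" not in log.data.columns:
        raise ValueError("assign_windows must run before aggregation")
    d = log.data
    all_specs: dict[str, VariableSpec] = {}
    for name, vt in log.value_types.items():
        if specs and name in specs:
            spec = specs[name]
            if spec.value_type != vt:
                raise ValueError(f"spec for {name!r} declares {spec.value_type}, log has {vt}")
            all_specs[name] = spec
        else:
            all_specs[name] = default_spec(name, vt)

    pieces = []
    keys = ["user_id", "window_index"]
    by_agg: dict[str, list[str]] = {}
    for name, spec in all_specs.items():
        by_agg.setdefault(spec.within_window_agg, []).append(name)

    for agg, names in by_agg.items():
        sub = d[d["variable"].isin(names)]
        if sub.empty:
            continue
        if agg == "mode":
            wide = sub.pivot_table(
                index=keys, columns="variable", values="value", aggfunc=_mode_earliest
            )
        elif agg == "last":
            # log is time-sorted, so "last" is the latest touchpoint in the window
            is_cat = sub["variable"].map(lambda v: all_specs[v].value_type) == CATEGORICAL
            vals = sub["numeric_value"].where(~is_cat, sub["value"])
            wide = (
                sub.assign(_v=vals)
                .groupby(keys + ["variable"], sort=False)["_v"]
                .last()
                .unstack("variable")
            )
        else:
            wide = sub.pivot_table(
                index=keys, columns="variable", values="numeric_value", aggfunc=agg
            )
        pieces.append(wide)

    full_index = pd.MultiIndex.from_frame(d[keys].drop_duplicates()).sortlevel()[0]
    full_index = full_index.set_names(keys)
    table = pd.concat([p.reindex(full_index) for p in pieces], axis=1) if pieces else pd.DataFrame(index=full_index)
    table = table.sort_index()
    vt = {name: all_specs[name].value_type for name in table.columns}
    return JourneyTable(
        data=table,
        window_days=log.window_days,
        origin=log.origin or "per_user_first",
        value_types=vt,
        specs=all_specs,
        origins=log.origins,
    )


def carry_forward(table: JourneyTable, features: Sequence[str] | None = None) -> JourneyTable:
    """Last observation carried forward, per user, for questionnaire-style
    variables: missing cells after a user's first observation take the last
    observed value; cells before the first observation stay missing.
    Idempotent."""
    if features is None:
        features = [n for n, s in table.specs.items() if s.carry_forward and n in table.data.columns]
    missing = [f for f in features if f not in table.data.columns]
    if missing:
        raise KeyError(f"carry_forward features not in table: {missing}")
    if not features:
        return table
    d = table.data.copy()
    d[list(features)] = d.groupby(level="user_id", sort=False)[list(features)].ffill()
    return replace(table, data=d)


def drop_constant_categoricals(table: JourneyTable) -> tuple[JourneyTable, list[str]]:
    """Remove categorical columns with at most one observed level.

    All-missing categorical columns count as zero-level and are removed.
    Returns the reduced table and the removal list.
    """
    removed = [
        c for c in table.columns_of_type(CATEGORICAL) if table.data[c].dropna().nunique() <= 1
    ]
    if removed:
        logger.info("removed %d single-level categorical column(s): %s", len(removed), removed)
    d = table.data.drop(columns=removed)
    vt = {k: v for k, v in table.value_types.items() if k not in removed}
    return replace(table, data=d, value_types=vt), removed


@dataclass
class UserFeatureTable:
    """One row per user; the input to the dropout classifiers.

    ``y`` codes dropout=1 / completer=0 (dropout is the positive class).
    ``core_cutoff`` records which per-core analysis the table belongs to.
    ``protected`` lists columns exempt from missingness deletion.
    """

    data: pd.DataFrame
    value_types: dict[str, str]
    y: pd.Series | None = None
    core_cutoff: int | None = None
    protected: set[str] = field(default_factory=set)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def numeric_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.value_types.get(c) != CATEGORICAL]

    def categorical_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.value_types.get(c) == CATEGORICAL]

    def with_columns(self, cols: pd.DataFrame, value_types: Mapping[str, str], protected: bool = False) -> "UserFeatureTable":
        overlap = [c for c in cols.columns if c in self.data.columns]
        base = self.data.drop(columns=overlap)  # new definitions win
        data = pd.concat([base, cols.reindex(self.data.index)], axis=1)
        vt = dict(self.value_types, **dict(value_types))
        prot = set(self.protected) | (set(cols.columns) if protected else set())
        return UserFeatureTable(data, vt, self.y, self.core_cutoff, prot)


EVENT_PREFIX_COMPLETED = "core_completed_"
EVENT_PREFIX_AVAILABLE = "core_available_"


def core_event_dates(log: TouchPointLog, prefix: str, n_cores: int = 7) -> pd.DataFrame:
    """Per-user dates of core milestone events (columns = core index 0..n-1).

    Milestones are event variables named ``<prefix><core>``; the first
    occurrence counts.  Users lacking the event have NaT.
    """
    d = log.data
    frames = {}
    for c in range(n_cores):
        sub = d[d["variable"] == f"{prefix}{c}"]
        frames[c] = sub.groupby("user_id")["timestamp"].min().dt.normalize()
    users = pd.Index(d["user_id"].unique(), name="user_id")
    return pd.DataFrame(frames, index=users)


def core_completion_dates(log: TouchPointLog, n_cores: int = 7) -> pd.DataFrame:
    return core_event_dates(log, EVENT_PREFIX_COMPLETED, n_cores)


def core_availability_dates(log: TouchPointLog, n_cores: int = 7) -> pd.DataFrame:
    return core_event_dates(log, EVENT_PREFIX_AVAILABLE, n_cores)


def user_level_aggregate(
    table: JourneyTable,
    labels: Mapping | pd.Series | None = None,
    core_cutoff: int | None = None,
    completion_dates: pd.DataFrame | None = None,
) -> UserFeatureTable:
    """Collapse each user's journey to a single feature row.

    With a ``core_cutoff`` c, only users who completed core c are eligible
    and only windows starting on or before that user's core-c completion
    date enter the aggregation; this reproduces the per-core analysis
    design with its non-increasing eligible N.  Each feature is aggregated
    by its spec's ``user_agg`` (mean / mode / sum / last over the user's
    windows, skipping missing cells).
    """
    d = table.data
    if core_cutoff is not None:
        if completion_dates is None:
            raise ValueError("core_cutoff requires completion_dates")
        done = completion_dates[core_cutoff].dropna()
        eligible = done.index
        n_excluded = len(table.users) - len(eligible)
        if n_excluded:
            logger.info("core %d: excluded %d user(s) without completion", core_cutoff, n_excluded)
        d = d[d.index.get_level_values("user_id").isin(eligible)]
        if table.origins is not None:
            uid = d.index.get_level_values("user_id")
            widx = d.index.get_level_values("window_index")
            max_widx = (
                (done.loc[uid].to_numpy() - table.origins.loc[uid].to_numpy())
                / np.timedelta64(1, "D")
            ) // table.window_days
            d = d[widx.to_numpy() <= max_widx]

    cols: dict[str, pd.Series] = {}
    grouped = d.groupby(level="user_id", sort=True)
    for name in d.columns:
        agg = table.specs[name].user_agg if name in table.specs else "mean"
        s = grouped[name]
        if agg == "mean":
            cols[name] = s.mean()
        elif agg == "sum":
            cols[name] = s.sum(min_count=1)
        elif agg == "last":
            cols[name] = s.last()  # last non-missing observation
        elif agg == "mode":
            cols[name] = s.agg(_mode_earliest)
    out = pd.DataFrame(cols, columns=list(d.columns))
    out.index.name = "user_id"

    y = None
    if labels is not None:
        lab = pd.Series(labels)
        y = lab.reindex(out.index).astype(float)
        if y.isna().any():
            missing = out.index[y.isna()].tolist()
            raise ValueError(f"labels missing for users: {missing[:5]}")
        y = y.astype(int)
    vt = {c: table.value_types.get(c, NUMERIC) for c in out.columns}
    protected = {n for n, s in table.specs.items() if s.protected and n in out.columns}
    return UserFeatureTable(out, vt, y=y, core_cutoff=core_cutoff, protected=protected)
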