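"""Engineered features: rolling-window aggregates, interaction terms and the
theory-driven catalog.

The catalog reproduces the 25 handcrafted / clinically important features of
an insomnia intervention: engagement indicators summed over days (logins,
emails, triggers, naps, alcohol, days since last contact), per-core
completion latencies taken as last observations, and sleep-timing contrasts
(awake-to-arise interval, preferred vs actual arise/bed times) averaged over
diary days.  Catalog features are *protected*: they are never deleted by
missingness filters, mirroring their theory-driven rationale.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .touchpoints import (
    NUMERIC,
    TouchPointLog,
    UserFeatureTable,
    core_availability_dates,
    core_completion_dates,
)

logger = logging.getLogger(__name__)

ROLLING_STATS = ("sum", "mean", "min", "max", "sd")


@dataclass(frozen=True)
class RollingSpec:
    """Rolling aggregation over ``w`` consecutive observations of one series.

    ``w`` counts observations (time steps), not calendar days; the sample
    (n-1) standard deviation is used, so ``sd`` at w=1 is undefined and
    reported missing.
    """

    name: str
    w: int
    stats: tuple[str, ...] = ROLLING_STATS

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("rolling window length w must be >= 1")
        bad = set(self.stats) - set(ROLLING_STATS)
        if bad:
            raise ValueError(f"unknown rolling stats: {sorted(bad)}")


def rolling_window_features(series: Sequence[float] | pd.Series, spec: RollingSpec) -> pd.DataFrame:
    """Aggregates over each run of ``spec.w`` consecutive observations.

    Output rows align to the last observation of each window, so the result
    has ``max(0, n - w + 1)`` rows; a window longer than the series yields
    no rows.  Column names follow the ``<name>_<stat><w>`` convention
    (e.g. ``mood_mean3``).
    """
    s = pd.Series(np.asarray(series, dtype=float))
    w = spec.w
    out = {}
    roll = s.rolling(window=w, min_periods=w)
    for stat in spec.stats:
        if stat == "sd":
            vals = roll.std(ddof=1)
        else:
            vals = getattr(roll, stat)()
        out[f"{spec.name}_{stat}{w}"] = vals
    res = pd.DataFrame(out)
    return res.iloc[w - 1:].reset_index(drop=True) if len(s) >= w else res.iloc[0:0]


def interaction_terms(
    table: UserFeatureTable | pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | str = "all",
):
    """Add elementwise products of numeric feature pairs as ``a_x_b`` columns.

    ``pairs="all"`` builds every unordered pair of numeric columns
    (p*(p-1)/2 new columns); the default elsewhere in the pipeline is an
    explicit pair list, since all-pairs expansion quickly dominates the
    feature space.  Missing values propagate.  A categorical member of a
    pair is an error.
    """
    df = table.data if isinstance(table, UserFeatureTable) else table
    if isinstance(table, UserFeatureTable):
        numeric = set(table.numeric_columns())
    else:
        numeric = set(df.select_dtypes(include=[np.number]).columns)
    if pairs == "all":
        pairs = list(itertools.combinations(sorted(numeric), 2))
    new = {}
    for a, b in pairs:
        for col in (a, b):
            if col not in df.columns:
                raise KeyError(f"interaction feature {col!r} not in table")
            if col not in numeric:
                raise ValueError(f"interaction requires numeric features; {col!r} is categorical")
        new[f"{a}_x_{b}"] = pd.to_numeric(df[a]) * pd.to_numeric(df[b])
    cols = pd.DataFrame(new, index=df.index)
    if isinstance(table, UserFeatureTable):
        return table.with_columns(cols, {c: NUMERIC for c in cols.columns})
    return pd.concat([df, cols], axis=1)


# ---------------------------------------------------------------------------
# daily grids and primitive event features


def _daily_grid(log: TouchPointLog) -> pd.DataFrame:
    """(user_id, date) frame spanning each user's first..last touchpoint day."""
    d = log.data
    dates = d["timestamp"].dt.normalize()
    span = dates.groupby(d["user_id"]).agg(["min", "max"])
    frames = [
        pd.DataFrame({"user_id": uid, "date": pd.date_range(lo, hi, freq="D")})
        for uid, (lo, hi) in span.iterrows()
    ]
    return pd.concat(frames, ignore_index=True)


def event_indicator(log: TouchPointLog, event_type: str, grid: pd.DataFrame | None = None) -> pd.Series:
    """Daily 0/1 indicator: 1 if at least one event of ``event_type``
    occurred that day.  Indexed by (user_id, date) over each user's
    observed day span."""
    if event_type not in log.value_types:
        raise KeyError(f"unknown event type {event_type!r}")
    if grid is None:
        grid = _daily_grid(log)
    d = log.data[log.data["variable"] == event_type]
    hits = set(zip(d["user_id"], d["timestamp"].dt.normalize()))
    idx = pd.MultiIndex.from_frame(grid[["user_id", "date"]])
    vals = np.fromiter(((u, t) in hits for u, t in idx), dtype=float, count=len(idx))
    return pd.Series(vals, index=idx, name=event_type)


def days_since_last_contact(
    log: TouchPointLog,
    sources: tuple[str, ...] = ("system", "self_report"),
    grid: pd.DataFrame | None = None,
) -> pd.Series:
    """Whole days since the most recent prior-or-same-day interaction.

    Any touchpoint from the configured sources counts as contact; days
    before a user's first contact are missing.  0 on contact days,
    incrementing by 1 across consecutive silent days.
    """
    if grid is None:
        grid = _daily_grid(log)
    d = log.data[log.data["source"].isin(sources)]
    contact_days = (
        d.assign(date=d["timestamp"].dt.normalize())[["user_id", "date"]].drop_duplicates()
    )
    g = grid.copy()
    key = pd.MultiIndex.from_frame(g[["user_id", "date"]])
    is_contact = key.isin(pd.MultiIndex.from_frame(contact_days))
    g["last_contact"] = g["date"].where(is_contact)
    g["last_contact"] = g.groupby("user_id", sort=False)["last_contact"].ffill()
    gap = (g["date"] - g["last_contact"]).dt.days.astype(float)
    return pd.Series(gap.to_numpy(), index=key, name="days_since_last_contact")


def completion_latency(log: TouchPointLog, n_cores: int = 7) -> pd.DataFrame:
    """Days each user needed to complete each core, plus the running average.

    Latency for core c = completion date - availability date in whole days;
    cores never completed stay missing.  ``avg_core_completion_time`` is
    the mean over all observed latencies (the running average evaluated at
    the last available core).  Completion before availability is an error.
    """
    avail = core_availability_dates(log, n_cores)
    done = core_completion_dates(log, n_cores)
    out = {}
    for c in range(n_cores):
        lat = (done[c] - avail[c]).dt.days.astype(float)
        if (lat.dropna() < 0).any():
            bad = lat.index[lat < 0][0]
            raise ValueError(f"core {c} completed before availability for user {bad!r}")
        out[f"core_{c}_completion_days"] = lat
    res = pd.DataFrame(out)
    res["avg_core_completion_time"] = res.mean(axis=1)
    return res


# ---------------------------------------------------------------------------
# clock arithmetic


def parse_clock_minutes(values: pd.Series) -> pd.Series:
    """'HH:MM' -> minutes after midnight; malformed entries become missing
    with a logged count."""
    s = values.astype("string").str.strip()
    m = s.str.extract(r"^(\d{1,2}):(\d{2})$")
    mins = pd.to_numeric(m[0]) * 60 + pd.to_numeric(m[1])
    mins = mins.where((pd.to_numeric(m[0]) < 24) & (pd.to_numeric(m[1]) < 60))
    n_bad = int((s.notna() & mins.isna()).sum())
    if n_bad:
        logger.warning("dropped %d malformed clock value(s)", n_bad)
    return mins.astype(float)


def clock_diff_minutes(a: pd.Series, b: pd.Series) -> pd.Series:
    """Shortest signed interval a -> b across midnight, in minutes (-720, 720]."""
    d = (b - a) % 1440.0
    return d.where(d <= 720.0, d - 1440.0)


def is_pm(minutes: pd.Series) -> pd.Series:
    """1 if a clock value falls at or after 12:00 noon, else 0."""
    return (minutes >= 720.0).astype(float).where(minutes.notna())


# ---------------------------------------------------------------------------
# the theory-driven catalog


@dataclass(frozen=True)
class CatalogFeature:
    """One theory-driven feature definition.

    ``kind`` selects the computation; ``params`` name the base variables or
    thresholds it uses; ``user_agg`` is the Table-style user-level
    aggregator.  Catalog features are always protected from
    missingness-threshold deletion.
    """

    name: str
    kind: str
    user_agg: str
    params: dict = field(default_factory=dict)
    protected: bool = True


def load_catalog(path) -> list[CatalogFeature]:
    """Read a YAML/JSON catalog file: a list of mappings mirroring
    :class:`CatalogFeature` fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    return [CatalogFeature(**entry) for entry in raw]


def save_catalog(catalog: Sequence[CatalogFeature], path) -> None:
    import yaml
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump([asdict(c) for c in catalog], fh, sort_keys=False)


def default_catalog(n_cores: int = 7) -> list[CatalogFeature]:
    """The shipped 25-entry catalog (8 sum + 12 last + 5 mean)."""
    cat = [
        # --- summed daily indicators / gaps -------------------------------
        CatalogFeature("days_since_last_contact", "gap_days", "sum"),
        CatalogFeature("sleep_duration_decreasing", "trend_flag", "sum",
                       {"variable": "sleep_duration"}),
        CatalogFeature("sleep_window_5_or_8h", "threshold_flag", "sum",
                       {"kind": "sleep_window", "hours": (5.0, 8.0), "tol_minutes": 15.0}),
        CatalogFeature("alcohol_day", "event_indicator", "sum", {"event": "alcohol"}),
        CatalogFeature("nap_day", "event_indicator", "sum", {"event": "nap"}),
        CatalogFeature("trigger_day", "event_indicator", "sum", {"event": "trigger_event"}),
        CatalogFeature("login_day", "event_indicator", "sum", {"event": "login"}),
        CatalogFeature("email_day", "event_indicator", "sum", {"event": "email_sent"}),
        # --- last-observation features ------------------------------------
        CatalogFeature("pref_arise_diff_core2_core3", "difference", "last",
                       {"kind": "per_core_clock_diff", "variable": "preferred_arise_time",
                        "cores": (2, 3)}),
        CatalogFeature("pref_arise_after_8am_core2", "threshold_flag", "last",
                       {"kind": "clock_after", "variable": "preferred_arise_time",
                        "core": 2, "minutes": 8 * 60}),
        CatalogFeature("avg_core_completion_time", "completion_latency", "last",
                       {"which": "average"}),
        *[
            CatalogFeature(f"core_{c}_completion_days", "completion_latency", "last",
                           {"which": c})
            for c in range(n_cores - 1)
        ],
        CatalogFeature("homework_core2_done", "event_indicator", "last",
                       {"event": "homework_core2", "ever": True}),
        CatalogFeature("days_without_diary", "gap_days", "last",
                       {"kind": "no_diary", "diary_variable": "sleep_duration"}),
        CatalogFeature("precipitating_factor_flag", "threshold_flag", "last",
                       {"kind": "category_in", "variable": "precipitating_factor",
                        "levels": ("major_life_event", "health_psychological")}),
        # --- diary-day means ----------------------------------------------
        CatalogFeature("awake_to_arise_minutes", "difference", "mean",
                       {"kind": "clock_diff", "a": "awake_time", "b": "arise_time"}),
        CatalogFeature("pref_vs_actual_arise_ampm", "difference", "mean",
                       {"kind": "ampm_diff", "a": "preferred_arise_time", "b": "arise_time"}),
        CatalogFeature("pref_vs_actual_arise_minutes", "difference", "mean",
                       {"kind": "clock_diff", "a": "preferred_arise_time", "b": "arise_time"}),
        CatalogFeature("pref_vs_actual_bedtime_minutes", "difference", "mean",
                       {"kind": "clock_diff", "a": "preferred_bedtime", "b": "bedtime"}),
        CatalogFeature("naptime_minutes", "base_mean", "mean", {"variable": "naptime_minutes"}),
    ]
    assert len(cat) == 25
    return cat


def _clock_by_day(log: TouchPointLog, variable: str) -> pd.Series:
    """Per (user, date) clock value in minutes; first report of the day wins."""
    d = log.data[log.data["variable"] == variable]
    mins = parse_clock_minutes(d["value"])
    frame = pd.DataFrame({
        "user_id": d["user_id"].to_numpy(),
        "date": d["timestamp"].dt.normalize().to_numpy(),
        "mins": mins.to_numpy(),
    })
    return frame.groupby(["user_id", "date"], sort=True)["mins"].first()


def apply_feature_catalog(
    table: UserFeatureTable,
    log: TouchPointLog,
    catalog: Sequence[CatalogFeature] | None = None,
    n_cores: int = 7,
) -> tuple[UserFeatureTable, dict[str, str]]:
    """Compute every catalog feature from the (cutoff-filtered) log and join
    them, protected, onto the user-level table.

    A catalog entry whose base variable is absent from the log yields an
    all-missing column with a warning rather than an error.  Returns the
    augmented table and a provenance map (column -> human-readable
    definition) for the reproducibility sidecar.
    """
    if catalog is None:
        catalog = default_catalog(n_cores)
    users = table.data.index
    grid = _daily_grid(log)
    latencies = completion_latency(log, n_cores)
    avail = core_availability_dates(log, n_cores)
    done = core_completion_dates(log, n_cores)

    cols: dict[str, pd.Series] = {}
    provenance: dict[str, str] = {}

    def user_agg(daily: pd.Series, how: str) -> pd.Series:
        g = daily.groupby(level=0)
        if how == "sum":
            return g.sum(min_count=1)
        if how == "mean":
            return g.mean()
        if how == "last":
            return g.last()
        raise ValueError(how)

    clock_cache: dict[str, pd.Series] = {}

    def clock(variable: str) -> pd.Series | None:
        if variable not in log.value_types:
            return None
        if variable not in clock_cache:
            clock_cache[variable] = _clock_by_day(log, variable)
        return clock_cache[variable]

    for feat in catalog:
        p = feat.params
        daily = None
        value: pd.Series | None = None
        desc = feat.kind
        try:
            if feat.kind == "event_indicator":
                ev = p["event"]
                if ev not in log.value_types:
                    raise KeyError(ev)
                daily = event_indicator(log, ev, grid)
                desc = f"daily 0/1 indicator of '{ev}' events"
                if p.get("ever"):
                    value = user_agg(daily, "sum").clip(upper=1.0)
                    desc = f"1 if any '{ev}' event ever occurred"
            elif feat.kind == "gap_days" and p.get("kind") == "no_diary":
                diary = event_indicator(log, p["diary_variable"], grid) if p["diary_variable"] in log.value_types else None
                if diary is None:
                    raise KeyError(p["diary_variable"])
                value = user_agg(1.0 - diary, "sum")
                desc = "number of observed days with no diary entry"
            elif feat.kind == "gap_days":
                daily = days_since_last_contact(log, grid=grid)
                desc = "days since the last contact (any interaction)"
            elif feat.kind == "trend_flag":
                var = p["variable"]
                if var not in log.value_types:
                    raise KeyError(var)
                d = log.data[log.data["variable"] == var]
                day = d["timestamp"].dt.normalize()
                per_core = {}
                for c in range(n_cores):
                    start = d["user_id"].map(avail[c])
                    end = d["user_id"].map(done[c])
                    in_core = (day >= start) & (day <= end.fillna(day.max()))
                    per_core[c] = d.loc[in_core].groupby("user_id")["numeric_value"].mean()
                pc = pd.DataFrame(per_core)
                dec = (pc.diff(axis=1) < 0).where(pc.notna() & pc.shift(axis=1).notna())
                value = dec.sum(axis=1, min_count=1)
                desc = f"count of core-to-core decreases in mean '{var}'"
            elif feat.kind == "threshold_flag" and p.get("kind") == "sleep_window":
                bt, ar = clock("bedtime"), clock("arise_time")
                if bt is None or ar is None:
                    raise KeyError("bedtime/arise_time")
                dur = clock_diff_minutes(*bt.align(ar, join="inner")) % 1440.0
                tol = p["tol_minutes"]
                flag = sum((dur - h * 60.0).abs() <= tol for h in p["hours"]).clip(upper=1)
                daily = flag.astype(float).where(dur.notna())
                desc = "daily flag: bed-to-arise window within 15 min of 5 h or 8 h"
            elif feat.kind == "threshold_flag" and p.get("kind") == "clock_after":
                cm = clock(p["variable"])
                if cm is None:
                    raise KeyError(p["variable"])
                d2 = cm.reset_index()
                start = d2["user_id"].map(avail[p["core"]])
                end = d2["user_id"].map(done[p["core"]])
                in_core = (d2["date"] >= start) & (d2["date"] <= end.fillna(d2["date"].max()))
                sub = d2.loc[in_core]
                core_mean = sub.groupby("user_id")["mins"].mean()
                value = (core_mean > p["minutes"]).astype(float).where(core_mean.notna())
                desc = f"1 if mean '{p['variable']}' in core {p['core']} is after {p['minutes']//60:02.0f}:00"
            elif feat.kind == "threshold_flag" and p.get("kind") == "category_in":
                var = p["variable"]
                if var not in log.value_types:
                    raise KeyError(var)
                d = log.data[log.data["variable"] == var]
                flag = d["value"].isin(p["levels"]).astype(float)
                value = flag.groupby(d["user_id"].to_numpy()).max()
                desc = f"1 if '{var}' includes {'/'.join(p['levels'])}"
            elif feat.kind == "completion_latency":
                which = p["which"]
                col = "avg_core_completion_time" if which == "average" else f"core_{which}_completion_days"
                value = latencies[col]
                desc = ("running average days to complete a core" if which == "average"
                        else f"days to complete core {which}")
            elif feat.kind == "difference" and p.get("kind") == "clock_diff":
                a, b = clock(p["a"]), clock(p["b"])
                if a is None or b is None:
                    raise KeyError(f"{p['a']}/{p['b']}")
                daily = clock_diff_minutes(*a.align(b, join="inner"))
                desc = f"shortest signed minutes from '{p['a']}' to '{p['b']}'"
            elif feat.kind == "difference" and p.get("kind") == "ampm_diff":
                a, b = clock(p["a"]), clock(p["b"])
                if a is None or b is None:
                    raise KeyError(f"{p['a']}/{p['b']}")
                aa, bb = a.align(b, join="inner")
                daily = is_pm(bb) - is_pm(aa)
                desc = f"difference of PM flags (noon boundary) of '{p['b']}' vs '{p['a']}'"
            elif feat.kind == "difference" and p.get("kind") == "per_core_clock_diff":
                cm = clock(p["variable"])
                if cm is None:
                    raise KeyError(p["variable"])
                c1, c2 = p["cores"]
                d2 = cm.reset_index()
                means = {}
                for c in (c1, c2):
                    start = d2["user_id"].map(avail[c])
                    end = d2["user_id"].map(done[c])
                    in_core = (d2["date"] >= start) & (d2["date"] <= end.fillna(d2["date"].max()))
                    means[c] = d2.loc[in_core].groupby("user_id")["mins"].mean()
                value = clock_diff_minutes(means[c1], means[c2])
                desc = f"minutes between mean '{p['variable']}' in core {c1} vs core {c2}"
            elif feat.kind == "base_mean":
                var = p["variable"]
                if var not in log.value_types:
                    raise KeyError(var)
                d = log.data[log.data["variable"] == var]
                frame = pd.DataFrame({
                    "user_id": d["user_id"].to_numpy(),
                    "date": d["timestamp"].dt.normalize().to_numpy(),
                    "v": d["numeric_value"].to_numpy(),
                })
                daily = frame.groupby(["user_id", "date"])["v"].mean()
                desc = f"daily mean of '{var}'"
            else:
                raise ValueError(f"unknown catalog kind {feat.kind!r}")
        except KeyError as e:
            logger.warning("catalog feature %r: base variable %s absent; column all-missing",
                           feat.name, e)
            cols[feat.name] = pd.Series(np.nan, index=users, dtype=float)
            provenance[feat.name] = f"{feat.kind} (base variable absent)"
            continue

        if value is None:
            value = user_agg(daily, feat.user_agg)
        cols[feat.name] = value.reindex(users).astype(float)
        provenance[feat.name] = f"{desc}; user aggregation: {feat.user_agg}"

    frame = pd.DataFrame(cols, index=users)
    out = table.with_columns(frame, {c: NUMERIC for c in frame.columns}, protected=True)
    return out, provenance
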