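"""Time-stratified case-crossover strata with lagged exposure histories.

Each case day is compared to referent days sharing its year, calendar month
and day of week, so season, long-term trend and weekday are differenced out
by design.  A stratum bundles the case day and its 3-4 referents, each with
the complete vector of lagged temperature-percentile exposures (lags 0..5),
the same-day relative humidity, and a federal-holiday indicator.  Multiple
qualifying visits in the same (county, day, demographic cell) enter as a
single stratum with a case-count weight, which is likelihood-equivalent to
replicating the stratum.

Strata in which any day (case or referent) lacks any lagged exposure or the
humidity value are dropped whole and logged, so referent-set size carries no
information about missingness.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_LAG = 5


def referent_days(case_date) -> list[dt.date]:
    """All other days in the case month with the same day of week, ascending."""
    d = pd.Timestamp(case_date)
    first = d.replace(day=1)
    offset = (d.dayofweek - first.dayofweek) % 7
    days_in_month = d.days_in_month
    out = []
    day = 1 + offset
    while day <= days_in_month:
        if day != d.day:
            out.append(dt.date(d.year, d.month, day))
        day += 7
    return out


def stratum_day_map(case_dates) -> pd.DataFrame:
    """Long map (case_date, date, is_case) for a set of distinct case days."""
    rows = []
    for d in pd.DatetimeIndex(pd.unique(pd.to_datetime(case_dates))):
        rows.append((d, d, True))
        rows.extend((d, pd.Timestamp(r), False) for r in referent_days(d))
    return pd.DataFrame(rows, columns=["case_date", "date", "is_case"])


@dataclass
class StrataBuildLog:
    """Accounting of where case weight went during stratum construction."""

    n_cases_in: int = 0                 # total qualifying visits
    n_strata_built: int = 0
    n_strata_dropped_missing: int = 0
    n_cases_dropped_missing: int = 0    # visit weight lost with those strata

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _day_level_table(county_days: pd.DataFrame, max_lag: int = MAX_LAG) -> pd.DataFrame:
    """Per (county, date): lag-0..max_lag percentiles, humidity, on a
    continuous daily calendar per county (gaps become missing lags)."""
    cd = county_days.copy()
    cd["date"] = pd.to_datetime(cd["date"])
    parts = []
    for county, sub in cd.groupby("county_id", sort=True):
        sub = sub.set_index("date").sort_index()
        full = pd.date_range(sub.index.min(), sub.index.max(), freq="D")
        sub = sub.reindex(full)
        block = pd.DataFrame(index=full)
        for lag in range(max_lag + 1):
            block[f"lag{lag}"] = sub["tmax_percentile"].shift(lag)
        block["rh"] = sub["rh_popwt"] if "rh_popwt" in sub else np.nan
        block["county_id"] = county
        parts.append(block.rename_axis("date").reset_index())
    return pd.concat(parts, ignore_index=True)


def build_strata(cases: pd.DataFrame, county_days: pd.DataFrame,
                 holidays=(), cell_cols: tuple[str, ...] = (),
                 max_lag: int = MAX_LAG) -> tuple[pd.DataFrame, StrataBuildLog]:
    """Assemble case-crossover strata for one cause group.

    Parameters
    ----------
    cases : DataFrame
        One row per qualifying visit, columns ``county_id``, ``date`` plus
        any of ``cell_cols`` (e.g. age_group, sex, region).  Rows are
        aggregated to case counts per (county, day, cell).
    county_days : DataFrame
        Exposure series with ``county_id, date, tmax_percentile, rh_popwt``;
        must extend at least ``max_lag`` days before each case date.
    holidays : iterable of dates
        Federal-holiday calendar; attached to every stratum day.

    Returns
    -------
    (strata, log) where ``strata`` is a long DataFrame with one row per
    stratum-day: ``stratum_id, county_id, case_date, date, is_case,
    case_count, lag0..lag{max_lag}, rh, holiday``.
    """
    log = StrataBuildLog(n_cases_in=len(cases))
    if cases.empty:
        cols = (["stratum_id", "county_id", "case_date", "date", "is_case",
                 "case_count"] + [f"lag{i}" for i in range(max_lag + 1)]
                + ["rh", "holiday"])
        return pd.DataFrame(columns=cols), log

    cases = cases.copy()
    cases["date"] = pd.to_datetime(cases["date"])
    keys = ["county_id", "date"] + [c for c in cell_cols if c in cases.columns]
    counts = cases.groupby(keys, sort=True).size().rename("case_count").reset_index()

    day_table = _day_level_table(county_days, max_lag)
    # pre-season availability check: the series must reach max_lag days
    # before the earliest case day of each county
    first_case = counts.groupby("county_id")["date"].min()
    first_avail = day_table.groupby("county_id")["date"].min()
    need = first_case - pd.Timedelta(days=max_lag)
    short = need[need < first_avail.reindex(need.index)]
    if len(short):
        county = short.index[0]
        raise ValueError(
            "exposure series lacks pre-season extension: earliest missing "
            f"date {short.iloc[0].date()} for county {county!r}")

    sdmap = stratum_day_map(counts["date"].unique())
    rows = counts.rename(columns={"date": "case_date"}).merge(
        sdmap, on="case_date", how="left")
    rows = rows.merge(day_table, on=["county_id", "date"], how="left")

    hol = pd.DatetimeIndex(pd.to_datetime(list(holidays)))
    rows["holiday"] = rows["date"].isin(hol).astype(float)

    lag_cols = [f"lag{i}" for i in range(max_lag + 1)]
    rows["_complete"] = rows[lag_cols + ["rh"]].notna().all(axis=1)
    strat_keys = ["county_id", "case_date"] + [c for c in cell_cols
                                               if c in counts.columns]
    rows["stratum_id"] = rows.groupby(strat_keys, sort=True).ngroup()
    keep = rows.groupby("stratum_id")["_complete"].transform("all")

    dropped = rows.loc[~keep & rows["is_case"], "case_count"]
    log.n_strata_dropped_missing = rows.loc[~keep, "stratum_id"].nunique()
    log.n_cases_dropped_missing = int(dropped.sum())

    out = rows[keep].drop(columns=["_complete"]).copy()
    out = out.sort_values(["stratum_id", "date"]).reset_index(drop=True)
    out["stratum_id"] = out.groupby("stratum_id", sort=True).ngroup()
    log.n_strata_built = out["stratum_id"].nunique()
    cols = (["stratum_id", "county_id", "case_date", "date", "is_case",
             "case_count"] + [c for c in cell_cols if c in out.columns]
            + lag_cols + ["rh", "holiday"])
    return out[cols], log


def write_strata(strata: pd.DataFrame, path) -> None:
    strata.to_csv(path, index=False, date_format="%Y-%m-%d")


def read_strata(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["case_date", "date"])
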