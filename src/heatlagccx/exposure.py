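"""Population-weighted county-day exposure series and percentile transforms.

Gridded daily maximum temperature (and relative humidity) at sub-county
points is aggregated to county-days with population weights; county-days
where more than 20% of the county population lacks data are excluded.  The
analysis window is the warm season (May-September); percentile tables are
built per county from warm-season days only, and a day of extreme heat is
one whose maximum temperature exceeds the county-specific 95th percentile.

The exposure series is additionally evaluated (through the warm-season
percentile table) on the 5 calendar days preceding each May 1, so that
early-May case days have complete lagged exposure histories rather than
being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WARM_MONTHS = (5, 6, 7, 8, 9)
COVERAGE_MIN = 0.8          # retain county-days with >= 80% population coverage
EXTREME_PERCENTILE = 95.0   # extreme heat: percentile strictly above this
MIN_PERCENTILE_DAYS = 30
PRE_SEASON_DAYS = 5         # lag depth required before May 1


def in_warm_season(dates) -> np.ndarray:
    """Boolean mask: date falls in May-September."""
    months = pd.DatetimeIndex(dates).month
    return np.isin(months, WARM_MONTHS)


# ---------------------------------------------------------------------------
# population weighting
# ---------------------------------------------------------------------------

def popweight_day(values: pd.DataFrame, weights: pd.DataFrame,
                  value_col: str = "tmax",
                  coverage_min: float = COVERAGE_MIN) -> tuple[float, float]:
    """Population-weighted average for one county-day.

    ``values`` holds rows (point_id, <value_col>) for a single county and
    date, possibly with missing values; ``weights`` holds (point_id,
    population).  Returns ``(weighted_value, coverage_fraction)`` where the
    weighted value is NaN when the covered population share falls below
    ``coverage_min`` (the "more than 20% missing" exclusion, boundary
    retained).
    """
    if len(weights) == 0:
        raise ValueError("no points for county")
    total_pop = float(weights["population"].sum())
    if total_pop <= 0:
        raise ValueError("total county population is zero")
    merged = weights[["point_id", "population"]].merge(
        values[["point_id", value_col]], on="point_id", how="left")
    ok = merged[value_col].notna()
    cov = float(merged.loc[ok, "population"].sum()) / total_pop
    if cov < coverage_min or not ok.any():
        return float("nan"), cov
    w = merged.loc[ok, "population"].to_numpy(float)
    v = merged.loc[ok, value_col].to_numpy(float)
    return float(np.sum(w * v) / np.sum(w)), cov


def aggregate_county_days(point_values: pd.DataFrame, weights: pd.DataFrame,
                          coverage_min: float = COVERAGE_MIN,
                          value_col: str = "tmax") -> pd.DataFrame:
    """Vectorized county-day aggregation of point values.

    Parameters
    ----------
    point_values : DataFrame with columns (point_id, date, <value_col>, [rh])
    weights : DataFrame with columns (point_id, county_id, population)

    Returns
    -------
    DataFrame with one row per (county_id, date): ``tmax_popwt``,
    ``rh_popwt`` (if an ``rh`` column is present), ``coverage_fraction``
    (for the primary metric) and ``in_warm_season``.
    """
    if weights.empty:
        raise ValueError("no points for county")
    if (weights["population"] < 0).any():
        raise ValueError("negative population weight")
    pop_by_county = weights.groupby("county_id")["population"].sum()
    if (pop_by_county <= 0).any():
        bad = pop_by_county[pop_by_county <= 0].index.tolist()
        raise ValueError(f"total county population is zero for {bad}")

    df = point_values.merge(
        weights[["point_id", "county_id", "population"]],
        on="point_id", how="left", validate="many_to_one")
    if df["county_id"].isna().any():
        missing = df.loc[df["county_id"].isna(), "point_id"].unique()[:5]
        raise ValueError(f"points without weights: {list(missing)}")
    df["date"] = pd.to_datetime(df["date"])

    out = {}
    cols = [value_col] + (["rh"] if "rh" in df.columns else [])
    gb = df.groupby(["county_id", "date"], sort=True)
    total = gb["population"].sum()
    for col in cols:
        covered = df["population"].where(df[col].notna(), 0.0)
        wsum = (covered * df[col].fillna(0.0)).groupby(
            [df["county_id"], df["date"]]).sum()
        psum = covered.groupby([df["county_id"], df["date"]]).sum()
        cov = psum / total
        val = (wsum / psum).where((cov >= coverage_min) & (psum > 0))
        out[col] = (val, cov)

    res = pd.DataFrame({
        "tmax_popwt": out[value_col][0],
        "coverage_fraction": out[value_col][1],
    })
    if "rh" in out:
        res["rh_popwt"] = out["rh"][0]
    res = res.reset_index()
    res["in_warm_season"] = in_warm_season(res["date"])
    return res


# ---------------------------------------------------------------------------
# percentile tables
# ---------------------------------------------------------------------------

@dataclass
class PercentileTable:
    """County-specific warm-season quantile/percentile transform.

    The quantile function interpolates linearly between order statistics at
    plotting positions ``100 * (k-1)/(n-1)`` (the common linear rule of
    mainstream numeric stacks); its inverse clamps to 0/100 outside the
    observed range.
    """

    county_id: object
    values: np.ndarray = field(repr=False)   # sorted warm-season tmax values

    def __post_init__(self):
        v = np.sort(np.asarray(self.values, dtype=float))
        if v.size < 2 or np.any(~np.isfinite(v)):
            raise ValueError("insufficient data for percentile table")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "_pos",
                           np.linspace(0.0, 100.0, v.size))

    def q(self, p) -> np.ndarray | float:
        """Quantile: temperature at percentile ``p`` in [0, 100]."""
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 100):
            raise ValueError("percentile outside [0, 100]")
        return np.interp(p, self._pos, self.values)[()]

    def p(self, t) -> np.ndarray | float:
        """Percentile of temperature ``t``; clamped to [0, 100] outside range."""
        return np.interp(np.asarray(t, dtype=float),
                         self.values, self._pos)[()]


def build_percentile_table(series: pd.DataFrame,
                           value_col: str = "tmax_popwt") -> PercentileTable:
    """Percentile table from one county's series.

    Only warm-season rows with a non-missing value (i.e. rows that passed
    the coverage rule) enter the table; at least 30 such days are required.
    """
    counties = series["county_id"].unique()
    if len(counties) != 1:
        raise ValueError("series must contain exactly one county")
    mask = series["in_warm_season"] & series[value_col].notna()
    vals = series.loc[mask, value_col].to_numpy(float)
    if vals.size < MIN_PERCENTILE_DAYS:
        raise ValueError("insufficient data for percentile table")
    return PercentileTable(counties[0], vals)


def flag_extreme(series: pd.DataFrame, table: PercentileTable,
                 value_col: str = "tmax_popwt") -> pd.DataFrame:
    """Attach ``tmax_percentile`` and ``extreme_heat`` to a county's series.

    Percentiles are evaluated for every non-missing day, including pre-season
    days needed for lagged histories; ``extreme_heat`` is strictly above the
    95th percentile.
    """
    counties = series["county_id"].unique()
    if len(counties) != 1 or counties[0] != table.county_id:
        raise ValueError(
            f"county mismatch: series {counties}, table {table.county_id!r}")
    out = series.copy()
    vals = out[value_col].to_numpy(float)
    pct = np.full(vals.shape, np.nan)
    ok = np.isfinite(vals)
    pct[ok] = np.atleast_1d(table.p(vals[ok]))
    out["tmax_percentile"] = pct
    out["extreme_heat"] = pct > EXTREME_PERCENTILE
    return out


def build_county_day_series(point_values: pd.DataFrame, weights: pd.DataFrame,
                            coverage_min: float = COVERAGE_MIN,
                            value_col: str = "tmax") -> pd.DataFrame:
    """Full exposure stage: aggregate, build per-county tables, flag extremes.

    Returns the county-day series with columns (county_id, date, tmax_popwt,
    rh_popwt, coverage_fraction, in_warm_season, tmax_percentile,
    extreme_heat), sorted by county and date.
    """
    agg = aggregate_county_days(point_values, weights, coverage_min, value_col)
    parts = []
    for county, sub in agg.groupby("county_id", sort=True):
        table = build_percentile_table(sub)
        parts.append(flag_extreme(sub, table))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_point_values(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.rename(columns={"tmax_f": "tmax", "tmean_f": "tmean",
                            "rh_pct": "rh"})
    df["date"] = pd.to_datetime(df["date"])
    if "rh" in df.columns:
        bad = df["rh"].dropna()
        if ((bad < 0) | (bad > 100)).any():
            raise ValueError("relative humidity outside [0, 100]")
    return df


def read_weights(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_county_days(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False, date_format="%Y-%m-%d")


def read_county_days(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    return df
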