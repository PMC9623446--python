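"""Synthetic study generator with a known exposure-lag-response truth.

Emulates the inputs of a national warm-season heat / pediatric ED-visit
study: gridded daily maximum temperature at sub-county points with
population weights, correlated relative humidity, federal holidays, a
county-to-climate-region lookup, and ED-visit claims drawn from a Poisson
intensity that combines calendar structure (month, day of week, holidays)
with a known distributed-lag temperature effect on the percentile scale.

The exposure truth is a piecewise-linear function f of the county-specific
temperature percentile with a single node at the median: f(50) = 0 and
f(95) = the configured cumulative log-OR, flat below the median.  Lag
weights w_ℓ (nonnegative, summing to one) spread the effect over lags 0..5,
so the generator's cumulative 95th-vs-50th rate ratio equals the configured
odds-ratio truth exactly.

Daily temperature at a point is seasonal curve + county offset + AR(1)
county anomaly + point-level noise; point-days are masked missing at a
configured rate so the coverage/exclusion rules are exercised.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import exposure as expo

NCA4_REGIONS = ("Northeast", "Southeast", "Midwest", "Northern Great Plains",
                "Southern Great Plains", "Northwest", "Southwest")

# representative ICD-10-CM codes per generated cause; heat-related events
# carry T67/E86/E87 in principal or secondary position
CAUSE_CODES = {
    "heat_related": {
        "principal_heat": ["T67.0XXA", "T67.9XXA", "E86.0", "E86.9", "E87.1"],
        "principal_other": ["R53.83", "R42", "N17.9"],
        "secondary_heat": ["T67.0XXA", "E86.0", "E87.0"],
    },
    "injury_poisoning": {"principal": ["S93.401A", "S52.501A", "S01.01XA",
                                       "T14.90XA", "S09.90XA"]},
    "respiratory": {"principal": ["J06.9", "J02.9", "J45.909", "J18.9"]},
    "signs_symptoms": {"principal": ["R10.9", "R50.9", "R05", "R11.2"]},
}


@dataclass(frozen=True)
class CauseTruth:
    """Ground truth for one generated cause group."""

    baseline_rate: float = 0.7      # expected visits per county-day at reference
    or_95v50: float = 1.0           # cumulative odds-ratio truth, 95th vs 50th


def _default_causes() -> dict:
    return {
        "heat_related": CauseTruth(baseline_rate=0.7, or_95v50=1.30),
        "injury_poisoning": CauseTruth(baseline_rate=2.0, or_95v50=1.0),
        "respiratory": CauseTruth(baseline_rate=1.0, or_95v50=1.0),
        "signs_symptoms": CauseTruth(baseline_rate=1.2, or_95v50=1.0),
    }


@dataclass
class SynthConfig:
    """Study-generator configuration; defaults define the reference study."""

    n_counties: int = 20
    points_per_county: int = 4
    years: tuple[int, ...] = (2016, 2017, 2018, 2019)
    # climate
    base_temp_f: float = 70.0
    seasonal_amplitude_f: float = 18.0
    peak_doy: int = 201                 # around July 20
    county_sd_f: float = 6.0
    ar_coef: float = 0.7
    ar_innovation_sd_f: float = 4.0
    point_noise_sd_f: float = 1.0
    rh_mean: float = 60.0
    rh_sd: float = 15.0
    rh_temp_corr: float = -0.4
    missing_rate: float = 0.002
    # visits
    causes: dict = field(default_factory=_default_causes)
    lag_weights: tuple[float, ...] = (0.50, 0.25, 0.12, 0.07, 0.04, 0.02)
    month_mult: dict = field(default_factory=lambda: {5: 1.0, 6: 1.05, 7: 1.10,
                                                      8: 1.05, 9: 0.95})
    dow_mult: tuple[float, ...] = (1.10, 1.00, 0.95, 0.95, 0.95, 1.00, 1.15)
    holiday_mult: float = 1.2
    age_group_probs: tuple[float, float, float] = (0.35, 0.35, 0.30)
    sex_probs: tuple[float, float] = (0.5, 0.5)
    heat_principal_prob: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError("AR(1) coefficient must be in (-1, 1)")
        w = np.asarray(self.lag_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("lag weights must be nonnegative and sum to 1")
        for name, c in self.causes.items():
            if c.baseline_rate <= 0:
                raise ValueError(f"baseline rate for {name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["causes"] = {k: asdict(v) for k, v in self.causes.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "causes" in d:
            d["causes"] = {k: CauseTruth(**v) for k, v in d["causes"].items()}
        for key in ("years", "lag_weights", "dow_mult", "age_group_probs",
                    "sex_probs"):
            if key in d:
                d[key] = tuple(d[key])
        if "month_mult" in d:
            d["month_mult"] = {int(k): float(v) for k, v in d["month_mult"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# calendars
# ---------------------------------------------------------------------------

def _nth_weekday(year, month, weekday, n) -> dt.date:
    d = dt.date(year, month, 1)
    offset = (weekday - d.weekday()) % 7
    return d + dt.timedelta(days=offset + 7 * (n - 1))


def _last_weekday(year, month, weekday) -> dt.date:
    if month == 12:
        d = dt.date(year, 12, 31)
    else:
        d = dt.date(year, month + 1, 1) - dt.timedelta(days=1)
    return d - dt.timedelta(days=(d.weekday() - weekday) % 7)


def _observed(d: dt.date) -> dt.date:
    if d.weekday() == 5:
        return d - dt.timedelta(days=1)
    if d.weekday() == 6:
        return d + dt.timedelta(days=1)
    return d


def federal_holidays(years) -> pd.DataFrame:
    """US federal holidays (observed dates) for the given years."""
    rows = []
    for y in years:
        rows += [
            (_observed(dt.date(y, 1, 1)), "New Year's Day"),
            (_nth_weekday(y, 1, 0, 3), "Martin Luther King Jr. Day"),
            (_nth_weekday(y, 2, 0, 3), "Washington's Birthday"),
            (_last_weekday(y, 5, 0), "Memorial Day"),
            (_observed(dt.date(y, 7, 4)), "Independence Day"),
            (_nth_weekday(y, 9, 0, 1), "Labor Day"),
            (_nth_weekday(y, 10, 0, 2), "Columbus Day"),
            (_observed(dt.date(y, 11, 11)), "Veterans Day"),
            (_nth_weekday(y, 11, 3, 4), "Thanksgiving Day"),
            (_observed(dt.date(y, 12, 25)), "Christmas Day"),
        ]
    df = pd.DataFrame(rows, columns=["date", "label"])
    df["date"] = pd.to_datetime(df["date"])
    return df.sort_values("date").reset_index(drop=True)


def study_dates(years) -> pd.DatetimeIndex:
    """Apr 26 - Sep 30 of each study year (5-day pre-season lag extension)."""
    parts = [pd.date_range(f"{y}-04-26", f"{y}-09-30", freq="D") for y in years]
    return parts[0].append(parts[1:]) if len(parts) > 1 else parts[0]


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def gen_climate(config: SynthConfig, rng: np.random.Generator | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (point_values, weights, regions).

    point_values: long table (point_id, date, tmax, rh) with missingness.
    weights: (point_id, county_id, population, x, y).
    regions: (county_id, region) round-robin over the NCA4 labels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nc, ppc = config.n_counties, config.points_per_county
    counties = [f"C{i:03d}" for i in range(nc)]
    county_offsets = rng.normal(0.0, config.county_sd_f, size=nc)

    weights = pd.DataFrame({
        "point_id": [f"C{i:03d}_P{j}" for i in range(nc) for j in range(ppc)],
        "county_id": np.repeat(counties, ppc),
        "population": rng.integers(500, 20000, size=nc * ppc),
        "x": rng.uniform(-100, -70, size=nc * ppc),
        "y": rng.uniform(25, 48, size=nc * ppc),
    })
    regions = pd.DataFrame({
        "county_id": counties,
        "region": [NCA4_REGIONS[i % len(NCA4_REGIONS)] for i in range(nc)],
    })

    dates = study_dates(config.years)
    nd = len(dates)
    doy = dates.dayofyear.to_numpy()
    seasonal = (config.base_temp_f + config.seasonal_amplitude_f
                * np.cos(2 * np.pi * (doy - config.peak_doy) / 365.25))

    # county AR(1) anomalies, restarted each year
    year_arr = dates.year.to_numpy()
    anom = np.empty((nc, nd))
    innov = rng.normal(0.0, config.ar_innovation_sd_f, size=(nc, nd))
    stat_sd = config.ar_innovation_sd_f / np.sqrt(1 - config.ar_coef ** 2)
    for t in range(nd):
        if t == 0 or year_arr[t] != year_arr[t - 1]:
            anom[:, t] = rng.normal(0.0, stat_sd, size=nc)
        else:
            anom[:, t] = config.ar_coef * anom[:, t - 1] + innov[:, t]

    county_tmax = seasonal[None, :] + county_offsets[:, None] + anom
    point_tmax = (np.repeat(county_tmax, ppc, axis=0)
                  + rng.normal(0.0, config.point_noise_sd_f, size=(nc * ppc, nd)))

    # humidity correlated with the temperature anomaly
    z = rng.normal(size=(nc * ppc, nd))
    anom_std = np.repeat(anom, ppc, axis=0) / max(stat_sd, 1e-9)
    rh = (config.rh_mean + config.rh_sd
          * (config.rh_temp_corr * anom_std
             + np.sqrt(1 - config.rh_temp_corr ** 2) * z))
    rh = np.clip(rh, 0.0, 100.0)

    mask = rng.random(size=(nc * ppc, nd)) < config.missing_rate
    point_tmax = np.where(mask, np.nan, point_tmax)
    rh = np.where(mask, np.nan, rh)

    pv = pd.DataFrame({
        "point_id": np.repeat(weights["point_id"].to_numpy(), nd),
        "date": np.tile(dates.to_numpy(), nc * ppc),
        "tmax": point_tmax.ravel(),
        "rh": rh.ravel(),
    })
    return pv, weights, regions


# ---------------------------------------------------------------------------
# visits
# ---------------------------------------------------------------------------

def percentile_effect(p, or_95v50: float) -> np.ndarray:
    """The truth function f: piecewise linear in percentile, node at 50.

    f(50) = 0, f(95) = log(or_95v50), flat below the median; f is the
    *cumulative* log rate-ratio scale — the per-lag contribution is
    ``w_ℓ * f``.
    """
    p = np.asarray(p, dtype=float)
    slope = np.log(or_95v50) / 45.0
    return np.where(p > 50.0, slope * (p - 50.0), 0.0)


def gen_visits(config: SynthConfig, county_days: pd.DataFrame,
               holidays: pd.DataFrame,
               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw ED-visit records from the Poisson intensity model.

    ``county_days`` must carry ``tmax_percentile`` (including the pre-season
    extension days).  Visits are generated for warm-season county-days with
    a complete 6-lag percentile history.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    w = np.asarray(config.lag_weights, dtype=float)
    max_lag = len(w) - 1

    cd = county_days.copy()
    cd["date"] = pd.to_datetime(cd["date"])
    parts = []
    for county, sub in cd.groupby("county_id", sort=True):
        sub = sub.set_index("date").sort_index()
        full = pd.date_range(sub.index.min(), sub.index.max(), freq="D")
        sub = sub.reindex(full)
        lags = np.column_stack([sub["tmax_percentile"].shift(l).to_numpy()
                                for l in range(max_lag + 1)])
        block = pd.DataFrame({"county_id": county, "date": full})
        for l in range(max_lag + 1):
            block[f"pct_lag{l}"] = lags[:, l]
        parts.append(block)
    day = pd.concat(parts, ignore_index=True)
    day = day[expo.in_warm_season(day["date"])]
    lag_cols = [f"pct_lag{l}" for l in range(max_lag + 1)]
    day = day.dropna(subset=lag_cols).reset_index(drop=True)

    months = day["date"].dt.month.map(config.month_mult).to_numpy(float)
    dows = np.asarray(config.dow_mult)[day["date"].dt.dayofweek.to_numpy()]
    hol = day["date"].isin(pd.to_datetime(holidays["date"])).to_numpy()
    cal = months * dows * np.where(hol, config.holiday_mult, 1.0)

    visits = []
    visit_counter = 0
    for cause, truth in config.causes.items():
        fvals = percentile_effect(day[lag_cols].to_numpy(float), truth.or_95v50)
        hazard = fvals @ w
        lam = truth.baseline_rate * cal * np.exp(hazard)
        counts = rng.poisson(lam)
        nz = np.flatnonzero(counts)
        if nz.size == 0:
            continue
        n_tot = int(counts[nz].sum())
        rep = np.repeat(nz, counts[nz])
        ages = _draw_ages(rng, n_tot, config.age_group_probs)
        sexes = rng.choice(["male", "female"], size=n_tot, p=config.sex_probs)
        princ, secs = _draw_codes(rng, cause, n_tot, config.heat_principal_prob)
        visits.append(pd.DataFrame({
            "visit_id": [f"V{visit_counter + i:08d}" for i in range(n_tot)],
            "date": day["date"].to_numpy()[rep],
            "age_years": ages,
            "sex": sexes,
            "county_id": day["county_id"].to_numpy()[rep],
            "principal_dx": princ,
            "secondary_dx": secs,
            "true_cause": cause,
        }))
        visit_counter += n_tot
    if not visits:
        return pd.DataFrame(columns=["visit_id", "date", "age_years", "sex",
                                     "county_id", "principal_dx",
                                     "secondary_dx", "true_cause"])
    out = pd.concat(visits, ignore_index=True)
    return out.sort_values(["date", "county_id", "visit_id"]).reset_index(drop=True)


def _draw_ages(rng, n, group_probs):
    group = rng.choice(3, size=n, p=np.asarray(group_probs, float))
    lo = np.array([0, 6, 13])[group]
    hi = np.array([6, 13, 18])[group]
    return lo + (rng.random(n) * (hi - lo)).astype(int)


def _draw_codes(rng, cause, n, heat_principal_prob):
    if cause == "heat_related":
        pools = CAUSE_CODES["heat_related"]
        as_principal = rng.random(n) < heat_principal_prob
        princ = np.where(as_principal,
                         rng.choice(pools["principal_heat"], size=n),
                         rng.choice(pools["principal_other"], size=n))
        sec_heat = rng.choice(pools["secondary_heat"], size=n)
        secs = [[] if ap else [sh] for ap, sh in zip(as_principal, sec_heat)]
        return princ.tolist(), secs
    pool = CAUSE_CODES.get(cause, {}).get("principal", ["R69"])
    return rng.choice(pool, size=n).tolist(), [[] for _ in range(n)]


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def make_study(config: SynthConfig, outdir) -> dict:
    """Generate and write the complete on-disk study bundle.

    Writes climate.csv, weights.csv, visits.csv, holidays.csv, regions.csv
    and truth.json (configuration + ground-truth ORs) to ``outdir``; returns
    the truth manifest.  Deterministic given ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    pv, weights, regions = gen_climate(config, rng)
    cds = expo.build_county_day_series(pv, weights)
    holidays = federal_holidays(config.years)
    visits = gen_visits(config, cds, holidays,
                        np.random.default_rng(config.seed + 1))

    pv.rename(columns={"tmax": "tmax_f", "rh": "rh_pct"}).to_csv(
        outdir / "climate.csv", index=False, date_format="%Y-%m-%d",
        float_format="%.4f")
    weights.to_csv(outdir / "weights.csv", index=False, float_format="%.4f")
    regions.to_csv(outdir / "regions.csv", index=False)
    holidays.to_csv(outdir / "holidays.csv", index=False,
                    date_format="%Y-%m-%d")
    from .claims import write_visits
    write_visits(visits.drop(columns=["true_cause"]), outdir / "visits.csv")
    visits[["visit_id", "true_cause"]].to_csv(outdir / "true_causes.csv",
                                              index=False)

    manifest = {
        "config": config.to_dict(),
        "true_or_95v50": {k: v.or_95v50 for k, v in config.causes.items()},
        "lag_weights": list(config.lag_weights),
        "n_visits": int(len(visits)),
        "seed": config.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=2))
    return manifest
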