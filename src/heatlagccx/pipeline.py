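"""End-to-end orchestration: simulate → exposure → classify → strata → fit →
predict → heterogeneity, with a single JSON run report.

Two entry points:

* :func:`simulate_and_fit` — in-memory path from a :class:`SynthConfig` to a
  fitted cumulative OR for one cause; used by the replicate studies
  (parameter recovery, null calibration) where file round-trips would
  dominate the runtime.
* :func:`run_pipeline` — file-based path driven by a :class:`RunConfig`,
  reading the CSV interfaces the other modules define and writing a report
  with provenance (config hash, input hashes, stratum drop counts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .basis import CrossBasisSpec
from .claims import (assign_strata, classify_visits, load_cause_groups,
                     read_visits, summarize_counts)
from .design import build_strata
from .exposure import (build_county_day_series, read_point_values,
                       read_weights, write_county_days)
from .fitting import fit_clogit
from .inference import (HeterogeneityResult, ORResult, curve, lag_curve,
                        mean_reference_percentile, or_at, wald_homogeneity)
from .synth import SynthConfig, federal_holidays, gen_climate, gen_visits

SUBGROUP_AXES = {"age": "age_group", "sex": "sex", "region": "region"}


# ---------------------------------------------------------------------------
# in-memory synthetic path
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Fitted OR for one cause on one synthetic study realization."""

    or_result: ORResult
    fit: object
    n_visits: int
    n_strata: int
    n_dropped_strata: int
    true_or: float


def simulate_study(config: SynthConfig):
    """Generate one study in memory: (county_days, labeled_visits, holidays).

    Visits are classified through the claims module (restricted to the
    cause groups the generator emits plus all-cause, for speed) and given
    demographic strata.
    """
    rng = np.random.default_rng(config.seed)
    pv, weights, regions = gen_climate(config, rng)
    cds = build_county_day_series(pv, weights)
    holidays = federal_holidays(config.years)
    visits = gen_visits(config, cds, holidays,
                        np.random.default_rng(config.seed + 1))
    wanted = {"all_cause"} | set(config.causes)
    groups = [g for g in load_cause_groups() if g.name in wanted]
    labeled = classify_visits(visits, groups)
    labeled = assign_strata(labeled, regions)
    return cds, labeled, holidays


def fit_cause(labeled: pd.DataFrame, county_days: pd.DataFrame,
              holidays: pd.DataFrame, cause: str,
              spec: CrossBasisSpec | None = None,
              include_humidity: bool = True,
              subset: pd.Series | None = None,
              cell_cols=("age_group", "sex", "region")):
    """Build strata and fit the conditional-logistic DLNM for one cause."""
    if spec is None:
        spec = CrossBasisSpec()
    mask = labeled[cause].astype(bool)
    if subset is not None:
        mask &= subset
    cases = labeled.loc[mask, ["county_id", "date"] +
                        [c for c in cell_cols if c in labeled.columns]]
    strata, log = build_strata(cases, county_days, holidays["date"],
                               cell_cols=tuple(cell_cols))
    if strata.empty:
        raise ValueError(f"no informative strata for cause {cause!r}")
    fit = fit_clogit(strata, spec,
                     n_dropped_strata=log.n_strata_dropped_missing,
                     include_humidity=include_humidity)
    return fit, log


def simulate_and_fit(config: SynthConfig, cause: str = "heat_related",
                     spec: CrossBasisSpec | None = None,
                     include_humidity: bool = True,
                     target_p: float = 95.0) -> StudyResult:
    """One replicate: simulate, run the pipeline, estimate the cumulative OR."""
    if spec is None:
        spec = CrossBasisSpec()
    cds, labeled, holidays = simulate_study(config)
    fit, log = fit_cause(labeled, cds, holidays, cause, spec,
                         include_humidity=include_humidity)
    res = or_at(fit, spec, target_p, None, "cumulative")
    return StudyResult(res, fit, int(labeled[cause].sum()),
                       fit.n_strata, log.n_strata_dropped_missing,
                       config.causes[cause].or_95v50)


# ---------------------------------------------------------------------------
# replicate studies (calibration / recovery experiments)
# ---------------------------------------------------------------------------

def replicate_config(or_true: float, seed: int,
                     doubled_calendar: bool = False) -> SynthConfig:
    """Scaled-down single-cause study used for replicate experiments.

    8 counties x 2 points x 2 warm seasons with a heat-related baseline of
    1.2 visits per county-day (~3,000 events per realization) — small enough
    that hundreds of replicates run in minutes, large enough that a single
    cumulative-OR estimate carries a usable standard error (~0.12 on the log
    scale).  ``doubled_calendar`` doubles every month and day-of-week
    multiplier, which the time-stratified design must difference out.
    """
    from .synth import CauseTruth
    month = {5: 1.0, 6: 1.05, 7: 1.10, 8: 1.05, 9: 0.95}
    dow = (1.10, 1.00, 0.95, 0.95, 0.95, 1.00, 1.15)
    if doubled_calendar:
        month = {k: 2 * v for k, v in month.items()}
        dow = tuple(2 * v for v in dow)
    return SynthConfig(
        n_counties=8, points_per_county=2, years=(2016, 2017),
        causes={"heat_related": CauseTruth(baseline_rate=1.2,
                                           or_95v50=or_true)},
        month_mult=month, dow_mult=dow, seed=seed)


def replicate_ors(n_reps: int, or_true: float = 1.30, seed0: int = 0,
                  doubled_calendar: bool = False) -> pd.DataFrame:
    """Cumulative 95th-vs-50th OR estimates over independent realizations."""
    rows = []
    for i in range(n_reps):
        cfg = replicate_config(or_true, seed0 + i, doubled_calendar)
        res = simulate_and_fit(cfg).or_result
        rows.append({"seed": seed0 + i, "or": res.or_point,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "log_or": res.log_or, "se": res.se_log_or})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a file-based pipeline run (YAML-serializable)."""

    points: str = ""
    weights: str = ""
    visits: str = ""
    holidays: str = ""
    regions: str = ""
    out_dir: str = "run_out"
    spec: dict = field(default_factory=dict)
    causes: tuple[str, ...] = ("heat_related",)
    subgroup_axes: tuple[str, ...] = ()
    contrasts: tuple[str, ...] = ("95:50",)
    metric: str = "tmax"                     # or "tmean"
    coverage_min: float = 0.8
    include_humidity: bool = True
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        d = yaml.safe_load(Path(path).read_text()) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("causes", "subgroup_axes", "contrasts"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        if not cfg.causes:
            raise ValueError("cause list is empty")
        for tok in cfg.contrasts:
            _parse_contrast(tok)
        return cfg


def _parse_contrast(token: str) -> tuple[float, object]:
    t, r = str(token).split(":")
    target = float(t)
    ref = r if r == "mean" else float(r)
    if not 0 <= target <= 100 or (ref != "mean" and not 0 <= float(r) <= 100):
        raise ValueError(f"contrast {token!r} outside [0, 100]")
    return target, ref


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage from CSV inputs and write report.json.

    Deterministic given the inputs and config; the report records the
    package version, a config hash, input-file hashes, exclusion counts and
    all OR contrasts (overall and per subgroup, with Wald homogeneity tests
    per axis).
    """
    if not config.causes:
        raise ValueError("cause list is empty")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = CrossBasisSpec.from_dict(config.spec) if config.spec else CrossBasisSpec()

    inputs = {k: getattr(config, k)
              for k in ("points", "weights", "visits", "holidays", "regions")}
    report = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
        "input_hashes": {k: _sha256(v) for k, v in inputs.items()},
        "spec": spec.to_dict(),
        "causes": {},
        "exclusions": {},
    }

    pv = read_point_values(config.points)
    value_col = "tmean" if config.metric == "tmean" else "tmax"
    if value_col not in pv.columns:
        raise ValueError(f"stage exposure: input lacks column {value_col!r}")
    weights = read_weights(config.weights)
    cds = build_county_day_series(pv, weights, config.coverage_min, value_col)
    write_county_days(cds, out / "county_days.csv")

    visits, n_rejected = read_visits(config.visits)
    report["exclusions"]["visits_rejected_age"] = n_rejected
    groups = load_cause_groups()
    labeled = classify_visits(visits, groups)
    regions = pd.read_csv(config.regions)
    labeled = assign_strata(labeled, regions)
    summarize_counts(labeled, groups).to_csv(out / "cause_counts.csv", index=False)

    holidays = pd.read_csv(config.holidays, parse_dates=["date"])
    mean_ref = mean_reference_percentile(cds)
    report["mean_reference_percentile"] = mean_ref

    rows = []
    for cause in config.causes:
        entry = {"contrasts": [], "subgroups": {}, "heterogeneity": {}}
        fit, log = fit_cause(labeled, cds, holidays, cause, spec,
                             include_humidity=config.include_humidity)
        entry["n_strata"] = fit.n_strata
        entry["n_dropped_strata"] = log.n_strata_dropped_missing
        entry["converged"] = fit.converged
        (out / f"fit_{cause}.json").write_text(fit.to_json())
        for token in config.contrasts:
            target, ref = _parse_contrast(token)
            ref_p = mean_ref if ref == "mean" else ref
            res = or_at(fit, spec, target, ref_p, "cumulative")
            entry["contrasts"].append({"contrast": token, **res.as_dict()})
            rows.append({"cause": cause, "subgroup": "overall",
                         "contrast": token, **res.as_dict()})
        curve(fit, spec).to_csv(out / f"curve_{cause}.csv", index=False)
        lag_df = lag_curve(fit, spec, 95.0)
        lag_df.to_csv(out / f"lag_curve_{cause}.csv", index=False)
        if config.make_plots:
            from .inference import plot_curve, plot_lag_curve
            plot_curve(curve(fit, spec), out / f"curve_{cause}.png", cause)
            plot_lag_curve(lag_df, out / f"lag_curve_{cause}.png", cause)

        for axis in config.subgroup_axes:
            col = SUBGROUP_AXES.get(axis, axis)
            ests = []
            for level in sorted(labeled[col].dropna().unique()):
                try:
                    gfit, _ = fit_cause(labeled, cds, holidays, cause, spec,
                                        include_humidity=config.include_humidity,
                                        subset=(labeled[col] == level))
                except ValueError:
                    continue
                res = or_at(gfit, spec, 95.0, None, "cumulative")
                entry["subgroups"].setdefault(axis, {})[str(level)] = res.as_dict()
                rows.append({"cause": cause, "subgroup": f"{axis}:{level}",
                             "contrast": "95:50", **res.as_dict()})
                if res.se_log_or > 0:
                    ests.append((str(level), res.log_or, res.se_log_or))
            if len(ests) >= 2:
                het = wald_homogeneity(ests)
                entry["heterogeneity"][axis] = het.as_dict()
        report["causes"][cause] = entry

    pd.DataFrame(rows).to_csv(out / "results.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
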