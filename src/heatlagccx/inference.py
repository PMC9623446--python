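"""Odds-ratio contrasts, exposure/lag-response curves, heterogeneity tests.

The fitted coefficient vector and covariance are turned into odds ratios by
the delta method: for a contrast vector c, log-OR = c'beta with standard
error sqrt(c' Sigma c) and a 95% CI using the normal quantile 1.96.  The
headline contrast compares a day of extreme heat (95th county-specific
temperature percentile) to a typical day (the median); 95th-vs-1st and
95th-vs-mean contrasts are provided for comparability with other studies.

Subgroup heterogeneity is assessed with the fixed-effects Wald statistic
Q = sum_i w_i (b_i - b̄)^2, w_i = 1/se_i^2, compared to chi-square with
(k - 1) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .basis import CrossBasisSpec, cumulative_contrast, lag_contrast
from .fitting import FitResult

Z95 = 1.96


@dataclass(frozen=True)
class ORResult:
    """One odds-ratio contrast with its 95% confidence interval."""

    target_percentile: float
    reference_percentile: float
    scope: str                  # "cumulative" or "lag<ℓ>"
    or_point: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float

    def as_dict(self) -> dict:
        return asdict(self)


def _contrast_vector(fit: FitResult, spec: CrossBasisSpec, target_p: float,
                     reference_p: float | None, scope: str) -> np.ndarray:
    if scope == "cumulative":
        cv = cumulative_contrast(target_p, spec, reference_p)
    elif scope.startswith("lag"):
        cv = lag_contrast(target_p, int(scope[3:]), spec, reference_p)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    n_cb = spec.n_columns
    if len(fit.beta) < n_cb or fit.column_names[:n_cb] != spec.column_names():
        raise ValueError("spec does not match the fitted design")
    c = np.zeros(len(fit.beta))
    c[:n_cb] = cv.vector
    return c


def or_at(fit: FitResult, spec: CrossBasisSpec, target_p: float,
          reference_p: float | None = None,
          scope: str = "cumulative") -> ORResult:
    """Odds ratio at ``target_p`` vs ``reference_p`` (default: spec reference)."""
    c = _contrast_vector(fit, spec, target_p, reference_p, scope)
    log_or = float(c @ fit.beta)
    var = float(c @ fit.cov @ c)
    se = float(np.sqrt(max(var, 0.0)))
    ref = spec.reference_percentile if reference_p is None else float(reference_p)
    return ORResult(float(target_p), ref, scope,
                    or_point=float(np.exp(log_or)),
                    ci_low=float(np.exp(log_or - Z95 * se)),
                    ci_high=float(np.exp(log_or + Z95 * se)),
                    log_or=log_or, se_log_or=se)


def curve(fit: FitResult, spec: CrossBasisSpec, grid=None,
          reference_p: float | None = None) -> pd.DataFrame:
    """Cumulative exposure-response curve over a percentile grid."""
    if grid is None:
        grid = np.arange(0.0, 100.5, 0.5)
    rows = [or_at(fit, spec, p, reference_p, "cumulative").as_dict()
            for p in np.asarray(grid, dtype=float)]
    return pd.DataFrame(rows)


def lag_curve(fit: FitResult, spec: CrossBasisSpec, target_p: float = 95.0,
              reference_p: float | None = None) -> pd.DataFrame:
    """Per-lag odds ratios for the target-vs-reference contrast."""
    rows = []
    for lag in range(spec.max_lag + 1):
        r = or_at(fit, spec, target_p, reference_p, f"lag{lag}").as_dict()
        r["lag"] = lag
        rows.append(r)
    return pd.DataFrame(rows)


def mean_reference_percentile(county_days: pd.DataFrame) -> float:
    """Percentile of the mean warm-season temperature, averaged over counties.

    Each county's warm-season mean daily maximum is mapped through that
    county's own percentile transform (rank among its warm-season days);
    the county values are averaged to give a single pooled reference for
    the 95th-vs-mean contrast.
    """
    from .exposure import build_percentile_table
    vals = []
    for _, sub in county_days.groupby("county_id"):
        table = build_percentile_table(sub)
        vals.append(float(table.p(float(np.mean(table.values)))))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# heterogeneity across strata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeterogeneityResult:
    """Fixed-effects Wald homogeneity test across subgroup estimates."""

    labels: tuple[str, ...]
    log_ors: tuple[float, ...]
    ses: tuple[float, ...]
    Q: float
    df: int
    p_value: float

    def as_dict(self) -> dict:
        return asdict(self)


def wald_homogeneity(groups) -> HeterogeneityResult:
    """Test homogeneity of per-group log-ORs.

    ``groups`` is a sequence of ``(label, log_or, se)`` (or ``(log_or, se)``)
    tuples.  Q is the inverse-variance weighted sum of squared deviations
    from the pooled mean, chi-square with (k-1) df under homogeneity.
    """
    parsed = []
    for i, g in enumerate(groups):
        if len(g) == 3:
            parsed.append((str(g[0]), float(g[1]), float(g[2])))
        else:
            parsed.append((f"group{i + 1}", float(g[0]), float(g[1])))
    if len(parsed) < 2:
        raise ValueError("at least two groups required")
    b = np.array([g[1] for g in parsed])
    se = np.array([g[2] for g in parsed])
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se ** 2
    bbar = float(np.sum(w * b) / np.sum(w))
    Q = float(np.sum(w * (b - bbar) ** 2))
    df = len(parsed) - 1
    p = float(stats.chi2.sf(Q, df))
    return HeterogeneityResult(tuple(g[0] for g in parsed),
                               tuple(b.tolist()), tuple(se.tolist()),
                               Q, df, p)


def log_or_se_from_ci(or_point: float, ci_low: float, ci_high: float
                      ) -> tuple[float, float]:
    """Recover (log_or, se) from a printed OR and 95% CI."""
    return float(np.log(or_point)), float((np.log(ci_high) - np.log(ci_low)) / (2 * Z95))


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_curve(curve_df: pd.DataFrame, path, title: str = "") -> None:
    """Exposure-response curve (cumulative OR vs percentile) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve_df["target_percentile"], curve_df["or_point"], color="C3")
    ax.fill_between(curve_df["target_percentile"], curve_df["ci_low"],
                    curve_df["ci_high"], alpha=0.25, color="C3")
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xlabel("daily maximum temperature percentile")
    ax.set_ylabel("cumulative OR")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lag_curve(lag_df: pd.DataFrame, path, title: str = "") -> None:
    """Lag-response (per-lag OR) plot to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(lag_df["lag"], lag_df["or_point"],
                yerr=[lag_df["or_point"] - lag_df["ci_low"],
                      lag_df["ci_high"] - lag_df["or_point"]],
                fmt="o-", capsize=3, color="C0")
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xlabel("lag (days)")
    ax.set_ylabel("OR at target vs reference percentile")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
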