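"""Conditional logistic regression over case-crossover strata.

The conditional likelihood of a stratum with one case day and m referent
days is the case day's share of the within-stratum softmax of the linear
predictor; stratum-constant covariates cancel.  Multiple same-day cases
enter through a case-count weight, equivalent to replicating the stratum.

    loglik(beta) = sum_s w_s [ x_case' beta - log sum_{d in s} exp(x_d' beta) ]

Maximization is Newton-Raphson with step halving on the observed
information, preceded by a pivoted-QR rank screen of the within-stratum
centered design (aliased columns — e.g. the structural collinearity of the
centered cross-basis, or covariates constant within every stratum — are
dropped and reported).  Falls back to BFGS if the information matrix is not
positive definite.  The covariance is the inverse observed information at
the optimum, embedded with zero rows/columns for dropped coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .basis import CrossBasisSpec, crossbasis_matrix, natural_spline_basis

LOGLIK_RTOL = 1e-9
GRAD_TOL = 1e-6
SEPARATION_BETA = 15.0   # on standardized columns
MAX_ITER = 100


# ---------------------------------------------------------------------------
# humidity adjustment spline
# ---------------------------------------------------------------------------

def rh_spline(rh_values, knots: tuple[float, float] | None = None,
              boundary: tuple[float, float] | None = None
              ) -> tuple[np.ndarray, dict]:
    """Natural cubic spline basis with 3 df for daily mean relative humidity.

    Interior knots default to the tertiles (33.3/66.7 percentiles) of the
    observed values, boundary knots to the observed min/max.  Returns the
    (n, 3) basis and the knot metadata needed to reproduce it.
    """
    rh = np.asarray(rh_values, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity outside [0, 100]")
    if knots is None:
        knots = tuple(np.percentile(rh, [100 / 3, 200 / 3]))
    if boundary is None:
        boundary = (float(rh.min()), float(rh.max()))
    lo, hi = boundary
    interior = [k for k in knots if lo < k < hi]
    if hi <= lo:  # constant humidity: return constant columns (dropped later)
        return np.zeros((rh.size, 3)), {"knots": list(knots),
                                        "boundary": [lo, hi]}
    B = natural_spline_basis(np.clip(rh, lo, hi), interior, boundary,
                             include_intercept=False)
    if B.shape[1] < 3:  # degenerate knot placement; pad constant columns
        B = np.hstack([B, np.zeros((rh.size, 3 - B.shape[1]))])
    return B, {"knots": [float(k) for k in knots], "boundary": [lo, hi]}


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

@dataclass
class StratumData:
    """Stacked design rows grouped by stratum (rows of a stratum contiguous)."""

    X: np.ndarray                       # (n_rows, p)
    starts: np.ndarray                  # row offset of each stratum
    case_idx: np.ndarray                # row index of the case day per stratum
    weights: np.ndarray                 # case_count per stratum
    column_names: list[str]
    rh_meta: dict = field(default_factory=dict)

    @property
    def n_strata(self) -> int:
        return len(self.starts)

    def validate(self):
        sizes = np.diff(np.r_[self.starts, len(self.X)])
        if np.any(sizes < 2):
            raise ValueError("stratum with no referent rows is uninformative")
        return self


def build_design(strata: pd.DataFrame, spec: CrossBasisSpec,
                 include_humidity: bool = True,
                 rh_knots=None, rh_boundary=None) -> StratumData:
    """Cross-basis + humidity-spline + holiday design from a strata table."""
    df = strata.sort_values(["stratum_id", "date"]).reset_index(drop=True)
    lag_cols = [f"lag{i}" for i in range(spec.max_lag + 1)]
    H = df[lag_cols].to_numpy(float)
    X = crossbasis_matrix(H, spec)
    names = spec.column_names()
    rh_meta = {}
    if include_humidity:
        R, rh_meta = rh_spline(df["rh"].to_numpy(float), rh_knots, rh_boundary)
        X = np.hstack([X, R])
        names = names + [f"rh_ns{i + 1}" for i in range(R.shape[1])]
    X = np.hstack([X, df["holiday"].to_numpy(float)[:, None]])
    names = names + ["holiday"]

    sid = df["stratum_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1]])
    is_case = df["is_case"].to_numpy(bool)
    case_idx = np.flatnonzero(is_case)
    if len(case_idx) != len(starts):
        raise ValueError("each stratum must have exactly one case day")
    weights = df.loc[is_case, "case_count"].to_numpy(float)
    return StratumData(X, starts, case_idx, weights, names, rh_meta).validate()


# ---------------------------------------------------------------------------
# likelihood, score, information
# ---------------------------------------------------------------------------

def _repeat_by_stratum(values: np.ndarray, data: StratumData) -> np.ndarray:
    sizes = np.diff(np.r_[data.starts, len(data.X)])
    return np.repeat(values, sizes)


def conditional_loglik(beta, data: StratumData) -> float:
    """Weighted conditional log-likelihood at ``beta``."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (data.X.shape[1],):
        raise ValueError(
            f"beta has length {beta.size}, design has {data.X.shape[1]} columns")
    eta = data.X @ beta
    m = np.maximum.reduceat(eta, data.starts)
    ex = np.exp(eta - _repeat_by_stratum(m, data))
    denom = np.add.reduceat(ex, data.starts)
    return float(np.sum(data.weights *
                        (eta[data.case_idx] - m - np.log(denom))))


def _loglik_parts(beta, data: StratumData):
    """(loglik, score, observed information) in one pass."""
    X, w = data.X, data.weights
    eta = X @ beta
    m = np.maximum.reduceat(eta, data.starts)
    ex = np.exp(eta - _repeat_by_stratum(m, data))
    denom = np.add.reduceat(ex, data.starts)
    ll = float(np.sum(w * (eta[data.case_idx] - m - np.log(denom))))
    p = ex / _repeat_by_stratum(denom, data)        # softmax within stratum
    S = np.add.reduceat(X * p[:, None], data.starts)  # stratum means (p, )
    grad = (w[:, None] * (X[data.case_idx] - S)).sum(axis=0)
    wp = _repeat_by_stratum(w, data) * p
    info = X.T @ (X * wp[:, None]) - (S * w[:, None]).T @ S
    return ll, grad, info


@dataclass
class FitResult:
    """Conditional-logistic fit: coefficients, covariance, diagnostics."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_strata: int
    n_dropped_strata: int
    converged: bool
    iterations: int
    column_names: list[str]
    dropped_columns: list[str]
    rh_meta: dict = field(default_factory=dict)
    message: str = ""

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def to_json(self) -> str:
        return json.dumps({
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "n_strata": self.n_strata,
            "n_dropped_strata": self.n_dropped_strata,
            "converged": self.converged,
            "iterations": self.iterations,
            "column_names": self.column_names,
            "dropped_columns": self.dropped_columns,
            "rh_meta": self.rh_meta,
            "message": self.message,
        })

    @classmethod
    def from_json(cls, s: str) -> "FitResult":
        d = json.loads(s)
        d["beta"] = np.asarray(d["beta"], dtype=float)
        d["cov"] = np.asarray(d["cov"], dtype=float)
        return cls(**d)


def _rank_screen(data: StratumData, tol: float = 1e-8) -> np.ndarray:
    """Indices of identifiable columns (pivoted QR on the within-stratum
    centered design)."""
    X = data.X
    sizes = np.diff(np.r_[data.starts, len(X)])
    means = np.add.reduceat(X, data.starts, axis=0) / sizes[:, None]
    Xc = X - np.repeat(means, sizes, axis=0)
    _, R, piv = scipy.linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * max(diag[0], 1e-300))) if diag.size else 0
    return np.sort(piv[:rank])


def fit_clogit(data: StratumData | pd.DataFrame,
               spec: CrossBasisSpec | None = None,
               n_dropped_strata: int = 0,
               max_iter: int = MAX_ITER, **design_kwargs) -> FitResult:
    """Maximize the conditional logistic likelihood.

    Accepts either a prepared :class:`StratumData` or a strata table plus a
    :class:`CrossBasisSpec` (forwarded to :func:`build_design`).
    """
    if isinstance(data, pd.DataFrame):
        if spec is None:
            raise ValueError("a CrossBasisSpec is required with a strata table")
        data = build_design(data, spec, **design_kwargs)
    if data.n_strata == 0:
        raise ValueError("no informative strata")

    p_full = data.X.shape[1]
    keep = _rank_screen(data)
    dropped = [data.column_names[j] for j in range(p_full) if j not in set(keep)]
    if keep.size == 0:
        raise ValueError("no identifiable covariates (all concordant strata)")

    # standardize retained columns by their within-stratum spread
    Xk = data.X[:, keep]
    sizes = np.diff(np.r_[data.starts, len(Xk)])
    means = np.add.reduceat(Xk, data.starts, axis=0) / sizes[:, None]
    Xc = Xk - np.repeat(means, sizes, axis=0)
    scale = Xc.std(axis=0)
    scale[scale == 0] = 1.0
    sub = StratumData(Xk / scale, data.starts, data.case_idx, data.weights,
                      [data.column_names[j] for j in keep])

    beta = np.zeros(keep.size)
    ll, grad, info = _loglik_parts(beta, sub)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = scipy.linalg.cho_solve(scipy.linalg.cho_factor(info), grad)
        except scipy.linalg.LinAlgError:
            res = scipy.optimize.minimize(
                lambda b: -conditional_loglik(b, sub), beta, method="BFGS",
                options={"gtol": GRAD_TOL, "maxiter": 500})
            beta = res.x
            ll, grad, info = _loglik_parts(beta, sub)
            converged = bool(res.success) and np.max(np.abs(grad)) < GRAD_TOL
            message = "quasi-Newton fallback: " + str(res.message)
            break
        new_beta, new_ll = beta + step, -np.inf
        for _ in range(30):
            new_ll = conditional_loglik(new_beta, sub)
            if new_ll >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        rel = abs(new_ll - ll) / (abs(ll) + 1e-12)
        beta = new_beta
        ll, grad, info = _loglik_parts(beta, sub)
        if np.max(np.abs(beta)) > SEPARATION_BETA:
            message = ("possible separation: standardized |beta| exceeds "
                       f"{SEPARATION_BETA}")
            converged = False
            break
        if rel < LOGLIK_RTOL and np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break

    try:
        cov_s = scipy.linalg.inv(info)
    except scipy.linalg.LinAlgError:
        cov_s = np.linalg.pinv(info)
        message = (message + "; " if message else "") + "singular information"
        converged = False

    beta_full = np.zeros(p_full)
    cov_full = np.zeros((p_full, p_full))
    beta_full[keep] = beta / scale
    cov_full[np.ix_(keep, keep)] = cov_s / np.outer(scale, scale)
    return FitResult(beta_full, cov_full, ll, data.n_strata, n_dropped_strata,
                     converged, it, data.column_names, dropped,
                     data.rh_meta, message)
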