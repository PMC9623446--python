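"""Distributed-lag non-linear (DLNM) cross-basis construction.

The exposure-lag-response surface is parameterized as a tensor product of a
quadratic B-spline in the exposure dimension (daily maximum temperature on
the county-specific percentile scale, 0-100) and a natural cubic spline over
lags 0..5 days.  The exposure basis is centered at a reference percentile
(default the median), so a day at the reference contributes a zero row and
odds-ratio contrasts against the reference are plain linear functionals of
the coefficient vector.

Conventions
-----------
* Column order of a cross-basis row is exposure-major: entry ``(j, k)`` sits
  at flat index ``j * n_lag_basis + k``.
* The exposure basis is the *full* B-spline basis (partition of unity before
  centering).  Centering makes the per-lag column blocks sum to zero, an
  exact collinearity that the conditional-logistic fitter screens out; the
  contrasts reported downstream are differences of realizable design rows
  and are therefore invariant to which aliased column is dropped.
* Interior lag knots default to equal spacing on the log scale of lag,
  ``exp(log(max_lag) * k / (K + 1))`` for ``k = 1..K`` — for two knots on
  lags 0..5 this puts them at ~1.71 and ~2.92 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space


# ---------------------------------------------------------------------------
# spline primitives
# ---------------------------------------------------------------------------

def bspline_basis(x, interior_knots, boundary, degree: int = 2) -> np.ndarray:
    """Full B-spline basis matrix (partition of unity) evaluated at ``x``.

    Parameters
    ----------
    x : array-like
        Evaluation points, all within ``[boundary[0], boundary[1]]``.
    interior_knots : sequence of float
        Strictly inside the boundary, non-decreasing.
    boundary : (float, float)
        Boundary knots; clamped (repeated ``degree + 1`` times).
    degree : int
        Spline degree (2 = quadratic, 3 = cubic).

    Returns
    -------
    ndarray of shape ``(len(x), len(interior_knots) + degree + 1)``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = float(boundary[0]), float(boundary[1])
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError(f"evaluation points outside boundary [{lo}, {hi}]")
    interior = np.asarray(interior_knots, dtype=float)
    if interior.size and (interior.min() <= lo or interior.max() >= hi):
        raise ValueError("interior knots must lie strictly inside the boundary")
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    return BSpline.design_matrix(x, t, degree).toarray()


def _natural_transform(interior, boundary, drop_intercept: bool) -> np.ndarray:
    """Coefficient-space transform mapping cubic B-splines to a natural basis.

    A natural cubic spline has zero second derivative at both boundary knots.
    We impose those two constraints on the full cubic B-spline coefficient
    space via its null space; optionally the constant function is excluded as
    well (its B-spline coefficient vector is all ones) to produce an
    intercept-free basis.
    """
    lo, hi = float(boundary[0]), float(boundary[1])
    interior = np.asarray(interior, dtype=float)
    t = np.r_[[lo] * 4, interior, [hi] * 4]
    nb = len(t) - 4
    rows = []
    for x0 in (lo, hi):
        r = np.empty(nb)
        for j in range(nb):
            c = np.zeros(nb)
            c[j] = 1.0
            r[j] = BSpline(t, c, 3).derivative(2)(x0)
        rows.append(r)
    if drop_intercept:
        rows.append(np.ones(nb))
    return null_space(np.vstack(rows))


def natural_spline_basis(x, interior_knots, boundary,
                         include_intercept: bool = False) -> np.ndarray:
    """Natural cubic spline basis evaluated at ``x``.

    With ``include_intercept`` the span contains the constant function and
    the basis has ``len(interior_knots) + 2`` columns; without it, the
    constant is excluded and the basis has ``len(interior_knots) + 1``
    columns (the degrees-of-freedom convention of regression splines).
    """
    B = bspline_basis(x, interior_knots, boundary, degree=3)
    Z = _natural_transform(interior_knots, boundary,
                           drop_intercept=not include_intercept)
    return B @ Z


# ---------------------------------------------------------------------------
# cross-basis specification
# ---------------------------------------------------------------------------

def log_spaced_lag_knots(n_knots: int, max_lag: int = 5) -> tuple[float, ...]:
    """Interior lag knots at equal intervals on the log scale of lag."""
    return tuple(float(np.exp(np.log(max_lag) * k / (n_knots + 1)))
                 for k in range(1, n_knots + 1))


@dataclass(frozen=True)
class CrossBasisSpec:
    """Specification of the DLNM cross-basis.

    Defaults mirror the primary model: quadratic B-spline in exposure with
    one interior knot at the 50th percentile, natural cubic lag spline with
    two interior knots log-spaced over lags 0-5, reference at the median.
    Sensitivity variants (2-3 exposure knots, 3 lag knots) are expressed by
    overriding the corresponding fields.
    """

    exposure_knots: tuple[float, ...] = (50.0,)
    exposure_degree: int = 2
    exposure_boundary: tuple[float, float] = (0.0, 100.0)
    max_lag: int = 5
    n_lag_knots: int = 2
    lag_knots: tuple[float, ...] | None = None
    lag_intercept: bool = True
    reference_percentile: float = 50.0

    def __post_init__(self):
        lo, hi = self.exposure_boundary
        for k in self.exposure_knots:
            if not lo < k < hi:
                raise ValueError("exposure knots must lie strictly inside the boundary")
        for k in self.resolved_lag_knots():
            if not 0.0 < k < self.max_lag:
                raise ValueError("lag knots must lie strictly inside (0, max_lag)")
        if not lo <= self.reference_percentile <= hi:
            raise ValueError("reference percentile outside exposure boundary")

    def resolved_lag_knots(self) -> tuple[float, ...]:
        if self.lag_knots is not None:
            return tuple(float(k) for k in self.lag_knots)
        return log_spaced_lag_knots(self.n_lag_knots, self.max_lag)

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.max_lag + 1)

    @property
    def n_exposure_basis(self) -> int:
        return len(self.exposure_knots) + self.exposure_degree + 1

    @property
    def n_lag_basis(self) -> int:
        return len(self.resolved_lag_knots()) + (2 if self.lag_intercept else 1)

    @property
    def n_columns(self) -> int:
        return self.n_exposure_basis * self.n_lag_basis

    def column_names(self) -> list[str]:
        return [f"cb_e{j}_l{k}" for j in range(self.n_exposure_basis)
                for k in range(self.n_lag_basis)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CrossBasisSpec":
        d = dict(d)
        for key in ("exposure_knots", "exposure_boundary", "lag_knots"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# basis evaluation
# ---------------------------------------------------------------------------

def exposure_basis(p, spec: CrossBasisSpec) -> np.ndarray:
    """Centered exposure basis at percentile(s) ``p``.

    The full quadratic B-spline basis minus its value at the reference
    percentile; the reference maps to the zero vector.  Accepts a scalar
    (returns a 1-d vector) or an array (returns a matrix).
    """
    scalar = np.isscalar(p) or np.ndim(p) == 0
    pa = np.atleast_1d(np.asarray(p, dtype=float))
    lo, hi = spec.exposure_boundary
    if np.any(pa < lo) or np.any(pa > hi):
        raise ValueError(f"percentile outside [{lo}, {hi}]")
    B = bspline_basis(pa, spec.exposure_knots, spec.exposure_boundary,
                      spec.exposure_degree)
    B0 = bspline_basis([spec.reference_percentile], spec.exposure_knots,
                       spec.exposure_boundary, spec.exposure_degree)
    out = B - B0
    return out[0] if scalar else out


def uncentered_exposure_basis(p, spec: CrossBasisSpec) -> np.ndarray:
    """Full (partition-of-unity) exposure basis, without centering."""
    return bspline_basis(np.atleast_1d(p), spec.exposure_knots,
                         spec.exposure_boundary, spec.exposure_degree)


def lag_basis(lag, spec: CrossBasisSpec) -> np.ndarray:
    """Natural cubic lag basis at integer lag(s); see ``CrossBasisSpec``."""
    scalar = np.isscalar(lag) or np.ndim(lag) == 0
    la = np.atleast_1d(np.asarray(lag, dtype=float))
    if np.any(la < 0) or np.any(la > spec.max_lag):
        raise ValueError(f"lag outside [0, {spec.max_lag}]")
    L = natural_spline_basis(la, spec.resolved_lag_knots(),
                             (0.0, float(spec.max_lag)),
                             include_intercept=spec.lag_intercept)
    return L[0] if scalar else L


def lag_basis_matrix(spec: CrossBasisSpec) -> np.ndarray:
    """Lag basis stacked over all integer lags, shape (max_lag+1, n_lag_basis)."""
    return lag_basis(spec.lags, spec)


# ---------------------------------------------------------------------------
# cross-basis rows and contrasts
# ---------------------------------------------------------------------------

def crossbasis_row(history, spec: CrossBasisSpec) -> np.ndarray:
    """Cross-basis design row for one day.

    ``history`` holds the percentile exposures at lags 0..max_lag (index ℓ is
    the exposure ℓ days before the day in question).  Entry ``(j, k)`` of the
    row is ``sum_ℓ exposure_basis(history[ℓ])_j * lag_basis(ℓ)_k``.
    """
    h = np.asarray(history, dtype=float)
    if h.shape != (spec.max_lag + 1,) or np.any(~np.isfinite(h)):
        raise ValueError(f"history must be a complete vector of {spec.max_lag + 1} lags")
    return crossbasis_matrix(h[None, :], spec)[0]

def crossbasis_matrix(histories, spec: CrossBasisSpec) -> np.ndarray:
    """Vectorized cross-basis rows for an (n, max_lag+1) array of histories."""
    H = np.asarray(histories, dtype=float)
    if H.ndim != 2 or H.shape[1] != spec.max_lag + 1:
        raise ValueError(f"histories must be (n, {spec.max_lag + 1})")
    if np.any(~np.isfinite(H)):
        raise ValueError("histories contain missing values")
    E = exposure_basis(H.ravel(), spec).reshape(H.shape[0], H.shape[1],
                                                spec.n_exposure_basis)
    L = lag_basis_matrix(spec)                     # (n_lags, n_lag_basis)
    return np.einsum("nlj,lk->njk", E, L).reshape(H.shape[0], spec.n_columns)


@dataclass(frozen=True)
class ContrastVector:
    """Coefficient-space vector c with log-OR = c @ beta for an exposure contrast."""

    target_percentile: float
    reference_percentile: float
    scope: str                     # "cumulative" or "lag<ℓ>"
    vector: np.ndarray = field(repr=False)


def cumulative_contrast(target_p: float, spec: CrossBasisSpec,
                        reference_p: float | None = None) -> ContrastVector:
    """Contrast for the log-OR cumulated over lags 0..max_lag.

    ``c[(j,k)] = (e(target) - e(ref))_j * sum_ℓ l(ℓ)_k``; with the default
    reference equal to the spec's centering point, ``e(ref)`` is zero.
    """
    ref = spec.reference_percentile if reference_p is None else float(reference_p)
    de = exposure_basis(target_p, spec) - exposure_basis(ref, spec)
    lsum = lag_basis_matrix(spec).sum(axis=0)
    return ContrastVector(float(target_p), ref, "cumulative",
                          np.outer(de, lsum).ravel())


def lag_contrast(target_p: float, lag: int, spec: CrossBasisSpec,
                 reference_p: float | None = None) -> ContrastVector:
    """Contrast for the log-OR at a single lag ℓ."""
    ref = spec.reference_percentile if reference_p is None else float(reference_p)
    de = exposure_basis(target_p, spec) - exposure_basis(ref, spec)
    lv = lag_basis(int(lag), spec)
    return ContrastVector(float(target_p), ref, f"lag{int(lag)}",
                          np.outer(de, lv).ravel())
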