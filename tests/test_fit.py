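"""Conditional logistic likelihood and Newton-Raphson fitter."""

import itertools

import numpy as np
import pandas as pd
import pytest

from heatlagccx.basis import CrossBasisSpec, natural_spline_basis
from heatlagccx.fitting import (StratumData, build_design, conditional_loglik,
                                fit_clogit, rh_spline)

from conftest import make_matched_pairs


def make_data(strata_list, weights=None):
    """StratumData from a list of (case_row, referent_rows) covariate arrays."""
    X, starts, case_idx = [], [], []
    offset = 0
    for case, refs in strata_list:
        starts.append(offset)
        case_idx.append(offset)
        X.append(np.atleast_2d(case))
        X.append(np.atleast_2d(refs))
        offset += 1 + len(np.atleast_2d(refs))
    w = np.ones(len(strata_list)) if weights is None else np.asarray(weights, float)
    Xs = np.vstack(X)
    return StratumData(Xs, np.array(starts), np.array(case_idx), w,
                       [f"x{i}" for i in range(Xs.shape[1])])


def brute_loglik(beta, strata_list, weights=None):
    """Direct summation over each stratum's denominator (independent oracle)."""
    w = np.ones(len(strata_list)) if weights is None else weights
    total = 0.0
    for (case, refs), wi in zip(strata_list, w):
        rows = np.vstack([np.atleast_2d(case), np.atleast_2d(refs)])
        etas = rows @ beta
        total += wi * (etas[0] - np.log(np.sum(np.exp(etas))))
    return total


class TestConditionalLoglik:
    def test_null_beta_uniform_probability(self):
        data = make_data([(np.array([1.0, 0.0]),
                           np.zeros((3, 2)))])
        assert conditional_loglik(np.zeros(2), data) == pytest.approx(np.log(0.25))

    def test_concordant_stratum_constant_in_beta(self):
        row = np.array([0.3, -1.2])
        data = make_data([(row, np.vstack([row, row]))])
        lls = [conditional_loglik(np.array(b), data)
               for b in [(0, 0), (1.5, -2.0), (-3.0, 0.7)]]
        assert np.ptp(lls) < 1e-12
        assert lls[0] == pytest.approx(np.log(1 / 3))

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(12)
        strata = [(rng.normal(size=2), rng.normal(size=(3, 2))),
                  (rng.normal(size=2), rng.normal(size=(4, 2)))]
        weights = np.array([1.0, 3.0])
        data = make_data(strata, weights)
        for _ in range(5):
            beta = rng.normal(size=2)
            assert conditional_loglik(beta, data) == pytest.approx(
                brute_loglik(beta, strata, weights), abs=1e-12)

    def test_dimension_mismatch(self):
        data = make_data([(np.zeros(2), np.zeros((3, 2)))])
        with pytest.raises(ValueError, match="columns"):
            conditional_loglik(np.zeros(3), data)


class TestFitClogit:
    def test_matched_pairs_closed_form(self, spec):
        # 1:1 pairs, binary covariate, 10 vs 5 discordant -> beta = ln 2
        strata = make_matched_pairs(10, 5, n_concordant=4)
        fit = fit_clogit(strata, spec)
        assert fit.converged
        j = fit.column_names.index("holiday")
        assert fit.beta[j] == pytest.approx(np.log(2.0), abs=1e-6)
        # closed-form variance for matched pairs: 1/n1 + 1/n2
        assert fit.cov[j, j] == pytest.approx(1 / 10 + 1 / 5, rel=1e-4)

    def test_grid_search_oracle_small_instance(self):
        rng = np.random.default_rng(5)
        beta_true = 0.8
        strata = []
        for _ in range(40):
            rows = rng.normal(size=4)
            probs = np.exp(rows * beta_true)
            case = rng.choice(4, p=probs / probs.sum())
            order = [case] + [i for i in range(4) if i != case]
            strata.append((rows[order[0]][None], rows[order[1:], None]))
        data = make_data(strata)
        fit = _fit_raw(data)
        grid = np.linspace(-3, 3, 6001)
        lls = [brute_loglik(np.array([b]), strata) for b in grid]
        assert fit[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_weighted_equals_replicated(self, spec):
        strata = make_matched_pairs(6, 3)
        # duplicate one stratum vs give it case_count 2
        dup = pd.concat([strata, strata[strata["stratum_id"] == 0]
                         .assign(stratum_id=99)], ignore_index=True)
        weighted = strata.copy()
        weighted.loc[weighted["stratum_id"] == 0, "case_count"] = 2
        f1 = fit_clogit(dup, spec)
        f2 = fit_clogit(weighted, spec)
        j = f1.column_names.index("holiday")
        assert f1.beta[j] == pytest.approx(f2.beta[j], abs=1e-8)
        assert f1.cov[j, j] == pytest.approx(f2.cov[j, j], rel=1e-6)

    def test_stratum_constant_shift_cancels(self):
        rng = np.random.default_rng(8)
        strata = [(rng.normal(size=2), rng.normal(size=(3, 2)))
                  for _ in range(30)]
        base = _fit_raw(make_data(strata))
        shifted = [(c + np.array([5.0, 0.0]), r + np.array([5.0, 0.0]))
                   for c, r in strata]
        out = _fit_raw(make_data(shifted))
        np.testing.assert_allclose(base, out, atol=1e-6)

    def test_concordant_only_design_rejected(self):
        row = np.array([1.0, 2.0])
        data = make_data([(row, np.vstack([row, row]))] * 3)
        with pytest.raises(ValueError, match="identifiable"):
            fit_clogit(data)

    def test_rank_deficient_columns_dropped_and_reported(self, spec):
        strata = make_matched_pairs(8, 4)
        fit = fit_clogit(strata, spec)
        # every cross-basis and humidity column is constant here; only the
        # binary covariate survives the screen
        assert set(fit.dropped_columns) >= set(spec.column_names())
        assert "holiday" not in fit.dropped_columns

    def test_separation_flagged(self):
        # perfectly separated binary covariate: case always exposed
        strata = [(np.array([1.0]), np.array([[0.0], [0.0]]))] * 10
        fit = fit_clogit(make_data(strata))
        assert not fit.converged
        assert "separation" in fit.message

    def test_agrees_with_statsmodels_conditional_logit(self):
        sm = pytest.importorskip("statsmodels.discrete.conditional_models")
        rng = np.random.default_rng(17)
        rows, groups, y = [], [], []
        beta_true = np.array([0.5, -0.3])
        for s in range(60):
            X = rng.normal(size=(4, 2))
            probs = np.exp(X @ beta_true)
            case = rng.choice(4, p=probs / probs.sum())
            for i in range(4):
                rows.append(X[i]); groups.append(s); y.append(1 if i == case else 0)
        X = np.asarray(rows)
        res = sm.ConditionalLogit(np.asarray(y), X,
                                  groups=np.asarray(groups)).fit(disp=False)
        strata = []
        for s in range(60):
            idx = [i for i in range(len(groups)) if groups[i] == s]
            case = [i for i in idx if y[i] == 1][0]
            refs = [i for i in idx if y[i] == 0]
            strata.append((X[case], X[refs]))
        ours = _fit_raw(make_data(strata), return_cov=True)
        np.testing.assert_allclose(ours[0], res.params, atol=1e-4)
        np.testing.assert_allclose(ours[1], res.cov_params(), rtol=1e-3,
                                   atol=1e-6)


def _fit_raw(data, return_cov=False):
    fit = fit_clogit(data)
    return (fit.beta, fit.cov) if return_cov else fit.beta


class TestRhSpline:
    def test_three_columns_any_length(self):
        rng = np.random.default_rng(2)
        for n in (10, 57, 300):
            B, meta = rh_spline(rng.uniform(20, 90, size=n))
            assert B.shape == (n, 3)
            assert len(meta["knots"]) == 2

    def test_natural_boundary_second_derivative(self):
        rng = np.random.default_rng(3)
        rh = rng.uniform(20, 90, size=200)
        _, meta = rh_spline(rh)
        lo, hi = meta["boundary"]
        h = 1e-3

        def basis_at(x):
            return natural_spline_basis([x], meta["knots"], (lo, hi))[0]

        for x0 in (lo + h, hi - h):
            second = (basis_at(x0 + h) - 2 * basis_at(x0) + basis_at(x0 - h)) / h ** 2
            assert np.max(np.abs(second)) < 1e-2

    def test_span_matches_independent_construction(self):
        from test_basis import span_distance, truncated_power_natural
        rng = np.random.default_rng(4)
        rh = np.sort(rng.uniform(20, 90, size=150))
        B, meta = rh_spline(rh)
        lo, hi = meta["boundary"]
        oracle = truncated_power_natural(rh, [lo] + list(meta["knots"]) + [hi])
        # intercept-free basis: spans agree after adding the constant column
        ours = np.column_stack([np.ones_like(rh), B])
        assert span_distance(ours, oracle) < 1e-7

    def test_constant_rh_yields_inert_columns(self):
        B, _ = rh_spline(np.full(20, 55.0))
        assert np.allclose(B, B[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rh_spline(np.array([50.0, 120.0]))
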