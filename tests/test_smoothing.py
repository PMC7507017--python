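"""Constrained smoothing: closed-form oracles, shape feasibility, KKT."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from germ import (
    DomainError,
    GerminationRecord,
    SmoothingConfig,
    ValidationError,
    eval_basis,
    fit_agdf,
    penalty_gram,
    solve_constrained_ls,
)
from germ.bspline import KnotSpec


def _objective(coeffs, collocation, penalty, y, w, alpha):
    resid = y - collocation @ coeffs
    return alpha * np.sum(w * resid**2) + (1 - alpha) * coeffs @ penalty @ coeffs


def _brute_force(collocation, penalty, y, w, alpha):
    """Independent oracle: SLSQP on the raw objective with explicit cone constraints."""
    d = collocation.shape[1]
    cons = [{"type": "ineq", "fun": lambda c, i=i: c[i + 1] - c[i]} for i in range(d - 1)]
    cons.append({"type": "ineq", "fun": lambda c: c[0]})
    best = None
    for start in (np.zeros(d), np.linspace(0, 1, d), np.full(d, 0.5)):
        res = minimize(
            _objective, start, args=(collocation, penalty, y, w, alpha),
            method="SLSQP", constraints=cons,
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def test_two_basis_toy_closed_form():
    """k=1 on [0,1] with data (0,0),(1,1): by hand b = (1/3, 2/3)."""
    spec = KnotSpec((0.0, 1.0), 1)
    C = eval_basis(spec, [0.0, 1.0])
    P = penalty_gram(spec, 1)
    b = solve_constrained_ls(C, P, np.array([0.0, 1.0]), np.ones(2), 0.5)
    assert b == pytest.approx([1 / 3, 2 / 3], abs=1e-6)


def test_constant_data_gives_constant_spline(config10):
    """Constant data admit a zero-roughness zero-residual feasible fit: s = c."""
    rec = GerminationRecord("const", tuple(range(1, 11)), (0.4,) * 10, 100)
    # the day-0 zero anchor would pull the fit down, so un-weight it
    cfg = SmoothingConfig(breaks=config10.breaks, weights=(0.0,) + (1.0,) * 10)
    agdf = fit_agdf(rec, cfg)
    grid = np.linspace(0, 10, 201)
    assert np.allclose(agdf(grid), 0.4, atol=1e-6)
    assert agdf.integral() == pytest.approx(4.0, abs=1e-5)


@pytest.mark.parametrize("factor", [0.1, 1.0, 7.0])
def test_scale_equivariance(kader_by_id, config10, factor):
    """Scaling the data by c > 0 scales the coefficients by exactly c."""
    rec = kader_by_id["D1"]
    base = np.asarray(fit_agdf(rec, config10).coeffs)
    # scale down so proportions stay in [0, 1] (equivariance is symmetric)
    c = factor if factor <= 1 else 1.0 / factor
    scaled = np.asarray(fit_agdf(rec.scaled(c), config10).coeffs)
    assert np.allclose(scaled, c * base, rtol=1e-8, atol=1e-12)


def test_unconstrained_optimum_recovered_when_feasible():
    """Strictly increasing smooth data: constraints inactive, NNLS = ridge LS."""
    spec = KnotSpec((0.0, 1.0), 1)
    C = eval_basis(spec, [0.0, 1.0])
    P = penalty_gram(spec, 1)
    y = np.array([0.2, 0.8])
    b = solve_constrained_ls(C, P, y, np.ones(2), 0.5)
    # unconstrained minimizer of 0.5(b2-b1)^2 + 0.5[(b1-.2)^2+(b2-.8)^2]
    H = 0.5 * (C.T @ C) + 0.5 * P
    expected = np.linalg.solve(H, 0.5 * C.T @ y)
    assert np.all(expected >= 0) and expected[1] >= expected[0]  # indeed feasible
    assert b == pytest.approx(expected, abs=1e-6)


def test_decreasing_data_fits_weighted_mean():
    """Strictly decreasing data: all increments pinned at 0, flat fit at the mean."""
    spec = KnotSpec((0.0, 1.0, 2.0), 1)
    C = eval_basis(spec, [0.0, 1.0, 2.0])
    P = penalty_gram(spec, 1)
    y = np.array([0.9, 0.5, 0.1])
    b = solve_constrained_ls(C, P, y, np.ones(3), 0.5)
    assert np.allclose(b, y.mean(), atol=1e-6)
    oracle = _brute_force(C, P, y, np.ones(3), 0.5)
    assert b == pytest.approx(oracle, abs=1e-4)


@pytest.mark.parametrize("alpha", [0.3, 0.5, 0.8])
def test_nnls_matches_bruteforce_qp(alpha):
    """On small bases the NNLS reformulation matches an SLSQP solve of the raw problem."""
    rng = np.random.default_rng(42)
    spec = KnotSpec((0.0, 1.0, 2.0, 3.0), 1)  # dimension 4
    pts = np.linspace(0, 3, 7)
    C = eval_basis(spec, pts)
    P = penalty_gram(spec, 1)
    y = np.clip(np.sort(rng.uniform(0, 1, pts.size)) + rng.normal(0, 0.1, pts.size), 0, 1)
    w = np.ones(pts.size)
    ours = solve_constrained_ls(C, P, y, w, alpha)
    oracle = _brute_force(C, P, y, w, alpha)
    assert _objective(ours, C, P, y, w, alpha) <= _objective(oracle, C, P, y, w, alpha) + 1e-10
    assert ours == pytest.approx(oracle, abs=1e-4)


def test_kkt_conditions_at_solution(kader_by_id, config10):
    """Stationarity of the NNLS solve: free coords have ~zero gradient, active ones >= 0."""
    rec = kader_by_id["A1"]
    spec = config10.knot_spec
    days = np.asarray(rec.days)
    C = eval_basis(spec, days)
    P = penalty_gram(spec, config10.penalty_order)
    y = np.asarray(rec.cumulative)
    b = solve_constrained_ls(C, P, y, np.ones(y.size), config10.alpha)
    g = np.concatenate([[b[0]], np.diff(b)])
    T = np.tril(np.ones((b.size, b.size)))
    # gradient of the g-problem: T^T (H b - alpha C^T W y), H the full Hessian
    H = config10.alpha * C.T @ C + (1 - config10.alpha) * P
    grad = T.T @ (H @ b - config10.alpha * C.T @ y)
    scale = max(1.0, np.abs(T.T @ (config10.alpha * C.T @ y)).max())
    free = g > 1e-10
    assert np.max(np.abs(grad[free])) <= 1e-6 * scale
    assert grad[~free].min() >= -1e-6 * scale


def test_shape_feasibility_on_all_fixture_fits(kader_agdfs):
    """min s >= -1e-8 and min s' >= -1e-8 on a 2001-point grid, every fit."""
    grid = np.linspace(0, 10, 2001)
    for agdf in kader_agdfs.values():
        coeffs = agdf.coeff_array
        assert coeffs.min() >= -1e-12
        assert np.diff(coeffs).min() >= -1e-12
        assert agdf(grid).min() >= -1e-8
        assert agdf.derivative_values(grid).min() >= -1e-8


def test_fitted_values_monotone_at_observation_days(kader_by_id, kader_agdfs):
    for name, agdf in kader_agdfs.items():
        days = np.asarray(kader_by_id[name].days)
        fitted = agdf(days)
        assert np.diff(fitted).min() >= -1e-8
        assert fitted.max() <= 1.05


def test_alpha_to_one_interpolates(kader_by_id, kader_agdfs, config10):
    """As alpha -> 1 the fit reproduces data sampled from a feasible spline."""
    truth = kader_agdfs["B1"]  # feasible curve representable in the basis
    spec = config10.knot_spec
    days = np.asarray(kader_by_id["B1"].days)
    y = truth(days)
    C = eval_basis(spec, days)
    P = penalty_gram(spec, config10.penalty_order)
    sse = []
    for alpha in (0.5, 0.99, 0.9999999):
        b = solve_constrained_ls(C, P, y, np.ones(y.size), alpha)
        sse.append(np.sum((C @ b - y) ** 2))
    assert sse[0] > sse[1] > sse[2]
    assert sse[2] < 1e-8


def test_validation_errors(config10):
    rec = GerminationRecord("ok", (0, 1, 2), (0.0, 0.1, 0.2), 10)
    with pytest.raises(ValidationError, match="weight"):
        fit_agdf(rec, SmoothingConfig(breaks=(0, 2, 5, 8, 10), weights=(0.0, 0.0, 0.0)))
    with pytest.raises(DomainError):
        fit_agdf(rec, SmoothingConfig(breaks=(0.0, 0.5, 1.0)))
    with pytest.raises(ValidationError, match="duplicate"):
        GerminationRecord("dup", (0, 1, 1, 2), (0.0, 0.1, 0.1, 0.2), 10)
    with pytest.raises(ValidationError, match="decrease"):
        GerminationRecord("dec", (0, 1, 2), (0.0, 0.3, 0.2), 10)
    with pytest.raises(ValidationError, match="alpha"):
        SmoothingConfig(breaks=(0, 2, 5, 8, 10), alpha=1.0)


def test_day_zero_anchor_prepended():
    rec = GerminationRecord("anchor", (1, 2, 3), (0.1, 0.2, 0.3), 10)
    assert rec.days[0] == 0.0 and rec.cumulative[0] == 0.0
    assert len(rec.days) == 4


def test_zero_record_fits_zero_spline(config10):
    rec = GerminationRecord("zero", tuple(range(11)), (0.0,) * 11, 100)
    agdf = fit_agdf(rec, config10)
    assert np.allclose(agdf.coeff_array, 0.0, atol=1e-9)
    assert agdf.integral() == pytest.approx(0.0, abs=1e-9)


def test_eval_agdf_domain_error(kader_agdfs):
    with pytest.raises(DomainError):
        kader_agdfs["A1"](np.array([-0.5]))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    counts=st.lists(st.floats(0, 20), min_size=3, max_size=10),
    scale=st.floats(0.1, 1.0),
)
def test_fit_always_feasible_property(counts, scale):
    """Any valid record yields a nonnegative nondecreasing coefficient vector."""
    counts = np.asarray(counts)
    total = 100
    if counts.sum() > total:
        counts = counts * (total / counts.sum()) * scale
    days = np.arange(1, counts.size + 1)
    rec = GerminationRecord.from_per_day_counts("h", days, counts, total)
    cfg = SmoothingConfig(breaks=tuple(np.linspace(0, counts.size, 5)), degree=3)
    agdf = fit_agdf(rec, cfg)
    c = agdf.coeff_array
    assert c.min() >= -1e-10
    assert np.diff(c).min() >= -1e-10
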