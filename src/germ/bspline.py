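"""Clamped B-spline bases on a break sequence.

Everything downstream (shape-constrained smoothing, the continuous
germination index, function-on-scalar regression) is expressed in a single
basis: B-splines of degree ``k`` on breakpoints ``a = lambda_0 < ... <
lambda_m = b`` with the boundary knots repeated ``k + 1`` times.  With that
clamping the basis has dimension ``(m) + k`` (``m + 1`` breaks), forms a
partition of unity on ``[a, b]``, and the spline interpolates its first and
last coefficients at the endpoints.

This module provides basis evaluation (with derivatives), exact integration,
and Gram/penalty matrices ``P[mu, nu] = int B_mu^(l) B_nu^(l) dt`` assembled
by Gauss-Legendre quadrature per knot interval, which is exact because the
integrand is piecewise polynomial of degree ``2(k - l)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

from .errors import DomainError, ValidationError

__all__ = [
    "KnotSpec",
    "build_knots",
    "eval_basis",
    "gram_matrix",
    "penalty_gram",
    "integrate_spline",
    "trapezoid_integral",
    "spline_to_dict",
    "spline_from_dict",
]

#: absolute slack allowed when checking that a point lies inside the domain
_DOMAIN_TOL = 1e-9


@dataclass(frozen=True)
class KnotSpec:
    """Break sequence plus degree; fully determines a clamped basis.

    Parameters
    ----------
    breaks
        Strictly increasing breakpoints (days), first entry is the domain
        start ``a``, last the domain end ``b``.  At least two are required.
    degree
        Polynomial degree ``k >= 1`` of the spline pieces (order ``k + 1``).
    """

    breaks: tuple
    degree: int

    def __post_init__(self):
        breaks = tuple(float(x) for x in self.breaks)
        object.__setattr__(self, "breaks", breaks)
        if int(self.degree) != self.degree or self.degree < 1:
            raise ValidationError(f"degree must be a positive integer, got {self.degree!r}")
        object.__setattr__(self, "degree", int(self.degree))
        if len(breaks) < 2:
            raise ValidationError("at least 2 breaks are required")
        diffs = np.diff(breaks)
        if np.any(diffs <= 0):
            j = int(np.argmax(diffs <= 0))
            raise ValidationError(
                f"breaks must be strictly increasing; breaks[{j}]={breaks[j]} "
                f">= breaks[{j + 1}]={breaks[j + 1]}"
            )

    @property
    def a(self) -> float:
        return self.breaks[0]

    @property
    def b(self) -> float:
        return self.breaks[-1]

    @property
    def dimension(self) -> int:
        """Number of basis functions: (#breaks - 1) + degree."""
        return len(self.breaks) - 1 + self.degree


def build_knots(spec: KnotSpec) -> np.ndarray:
    """Extended (clamped) knot sequence: k extra copies of each boundary.

    The returned sequence has length ``#breaks + 2k`` and boundary knots of
    total multiplicity ``k + 1``, so ``len(knots) - k - 1`` equals
    :attr:`KnotSpec.dimension`.
    """
    k = spec.degree
    return np.concatenate([np.full(k, spec.a), spec.breaks, np.full(k, spec.b)])


def _check_domain(spec: KnotSpec, pts: np.ndarray) -> None:
    scale = max(1.0, abs(spec.a), abs(spec.b))
    if pts.size and (pts.min() < spec.a - _DOMAIN_TOL * scale or pts.max() > spec.b + _DOMAIN_TOL * scale):
        bad = pts[(pts < spec.a - _DOMAIN_TOL * scale) | (pts > spec.b + _DOMAIN_TOL * scale)][0]
        raise DomainError(f"point {bad} outside the spline domain [{spec.a}, {spec.b}]")


def eval_basis(spec: KnotSpec, points, deriv_order: int = 0) -> np.ndarray:
    """Collocation matrix of the basis (or a derivative) at ``points``.

    Rows are evaluation points, columns basis functions.  For
    ``deriv_order = 0`` each row sums to one (partition of unity); for
    ``deriv_order >= 1`` each row sums to zero.
    """
    if deriv_order < 0 or deriv_order > spec.degree:
        raise ValidationError(
            f"deriv_order must be in [0, {spec.degree}], got {deriv_order}"
        )
    pts = np.atleast_1d(np.asarray(points, dtype=float))
    _check_domain(spec, pts)
    knots = build_knots(spec)
    d = spec.dimension
    out = np.empty((pts.size, d))
    for j in range(d):
        coef = np.zeros(d)
        coef[j] = 1.0
        bj = BSpline(knots, coef, spec.degree, extrapolate=True)
        if deriv_order:
            bj = bj.derivative(deriv_order)
        out[:, j] = bj(pts)
    return out


def gram_matrix(spec: KnotSpec, deriv_order: int = 0) -> np.ndarray:
    """Exact Gram matrix ``int_a^b B_mu^(l)(t) B_nu^(l)(t) dt``.

    Assembled interval by interval with Gauss-Legendre nodes; the number of
    nodes is chosen so the rule is exact for the piecewise-polynomial
    integrand of degree ``2 (k - l)``.
    """
    if deriv_order < 0 or deriv_order > spec.degree:
        raise ValidationError(
            f"deriv_order must be in [0, {spec.degree}], got {deriv_order}"
        )
    npts = spec.degree - deriv_order + 1  # exact for degree 2(k-l) <= 2*npts - 1
    x, w = leggauss(npts)
    d = spec.dimension
    gram = np.zeros((d, d))
    for lo, hi in zip(spec.breaks[:-1], spec.breaks[1:]):
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        basis = eval_basis(spec, mid + half * x, deriv_order)
        gram += half * basis.T @ (w[:, None] * basis)
    return 0.5 * (gram + gram.T)


def penalty_gram(spec: KnotSpec, penalty_order: int) -> np.ndarray:
    """Roughness-penalty matrix: Gram matrix of the l-th derivative basis.

    The quadratic form ``c^T P c`` equals the integrated squared l-th
    derivative of the spline with coefficients ``c``; for ``l = 1`` its null
    space is the constant coefficient vector.
    """
    if not 1 <= penalty_order <= spec.degree:
        raise ValidationError(
            f"penalty order must satisfy 1 <= l <= degree = {spec.degree}, "
            f"got {penalty_order}"
        )
    return gram_matrix(spec, penalty_order)


def _as_bspline(coeffs, spec: KnotSpec) -> BSpline:
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (spec.dimension,):
        raise ValidationError(
            f"expected {spec.dimension} coefficients for this basis, got {coeffs.shape}"
        )
    return BSpline(build_knots(spec), coeffs, spec.degree, extrapolate=True)


def integrate_spline(coeffs, spec: KnotSpec) -> float:
    """Exact integral of the spline over [a, b] via the antiderivative."""
    return float(_as_bspline(coeffs, spec).integrate(spec.a, spec.b))


def trapezoid_integral(coeffs, spec: KnotSpec, num: int = 10_001) -> float:
    """Composed-trapezoid integral on a uniform grid (cross-check / option)."""
    grid = np.linspace(spec.a, spec.b, num)
    return float(np.trapezoid(_as_bspline(coeffs, spec)(grid), grid))


def spline_to_dict(coeffs, spec: KnotSpec) -> dict:
    """JSON-serializable form: {degree, breaks, coefficients}."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (spec.dimension,):
        raise ValidationError("coefficient length does not match the basis dimension")
    return {
        "degree": spec.degree,
        "breaks": list(spec.breaks),
        "coefficients": coeffs.tolist(),
    }


def spline_from_dict(payload: dict):
    """Inverse of :func:`spline_to_dict`; returns ``(coeffs, spec)``."""
    try:
        spec = KnotSpec(tuple(payload["breaks"]), int(payload["degree"]))
        coeffs = np.asarray(payload["coefficients"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed spline payload: {exc}") from exc
    if coeffs.shape != (spec.dimension,):
        raise ValidationError(
            f"expected {spec.dimension} coefficients, got {coeffs.size}"
        )
    return coeffs, spec


def spline_to_json(coeffs, spec: KnotSpec) -> str:
    return json.dumps(spline_to_dict(coeffs, spec))


def spline_from_json(text: str):
    return spline_from_dict(json.loads(text))
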