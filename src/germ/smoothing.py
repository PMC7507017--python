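"""Nonnegative, nondecreasing optimal smoothing splines (AGDFs).

A cumulative germination record gives data pairs ``(t_j, y_j)`` with ``y``
the proportion of planted seeds germinated by day ``t_j``.  The absolute
germination distribution function (AGDF) is the spline ``s`` minimizing

    J_l(s) = (1 - alpha) * int_a^b (s^(l)(t))^2 dt
             + alpha * sum_j w_j (y_j - s(t_j))^2

subject to ``s(t) >= 0`` and ``s'(t) >= 0`` on the whole domain.  Unlike a
distribution function, the AGDF need not reach 1: dormant or dead seeds
leave the curve below its ceiling.

Shape constraints are enforced through the standard sufficient condition on
B-spline coefficients: the derivative of a degree-k spline is a degree-(k-1)
spline whose coefficients are positive multiples of consecutive coefficient
differences, so nondecreasing coefficients give a nondecreasing spline, and
together with a nonnegative first coefficient, a nonnegative spline.
Substituting ``b = T g`` (T the lower-triangular cumulative-sum map, g the
vector of the first coefficient followed by increments) turns the whole
problem into one canonical nonnegative least-squares solve::

    min_g  || [ sqrt(alpha) W^{1/2} C T ]      [ sqrt(alpha) W^{1/2} y ] ||^2
           || [ sqrt(1-alpha) R T      ] g  -  [ 0                     ] ||

with C the collocation matrix, P = R^T R the penalty Gram matrix (R from a
symmetric eigendecomposition, tiny negative eigenvalues clipped at zero),
solved by ``scipy.optimize.nnls``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from . import bspline
from .bspline import KnotSpec
from .errors import DomainError, NumericalError, ValidationError

__all__ = [
    "SmoothingConfig",
    "GerminationRecord",
    "Agdf",
    "fit_agdf",
    "solve_constrained_ls",
    "eval_agdf",
    "default_breaks",
]

logger = logging.getLogger("germ")

#: feasibility tolerance for the shape constraints on dense grids
FEASIBILITY_TOL = 1e-8
#: Karush-Kuhn-Tucker tolerance, scaled by ||A^T z||_inf
KKT_TOL = 1e-6


def default_breaks(last_day: float) -> tuple:
    """Five-knot break sequence for a germination experiment ending at ``last_day``.

    The two standard experimental designs (10-day and 28-day scoring) use
    the unevenly spaced {0, 2, 5, 8, 10} and the evenly spaced
    {0, 7, 14, 21, 28}; any other horizon gets five equally spaced knots.
    """
    if last_day == 10:
        return (0.0, 2.0, 5.0, 8.0, 10.0)
    if last_day == 28:
        return (0.0, 7.0, 14.0, 21.0, 28.0)
    return tuple(np.linspace(0.0, float(last_day), 5))


@dataclass(frozen=True)
class SmoothingConfig:
    """Parameters of the smoothing functional.

    Attributes
    ----------
    breaks
        Break sequence of the spline basis (days); spans the domain [a, b].
    degree
        Spline degree ``k`` (default 5, quintic).
    penalty_order
        Derivative order ``l`` in the roughness term (default 1).
    alpha
        Tradeoff in (0, 1): weight ``alpha`` on data fidelity, ``1 - alpha``
        on roughness.  0.5 is an even compromise and the default.
    weights
        Optional per-observation nonnegative weights; default all ones.
    """

    breaks: tuple
    degree: int = 5
    penalty_order: int = 1
    alpha: float = 0.5
    weights: Optional[tuple] = None

    def __post_init__(self):
        object.__setattr__(self, "breaks", tuple(float(x) for x in self.breaks))
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie strictly in (0, 1), got {self.alpha}")
        if not 1 <= self.penalty_order <= self.degree - 1:
            raise ValidationError(
                f"penalty_order must satisfy 1 <= l <= degree-1, got {self.penalty_order}"
            )
        if self.weights is not None:
            w = tuple(float(x) for x in self.weights)
            if any(x < 0 for x in w):
                raise ValidationError("weights must be nonnegative")
            if not any(x > 0 for x in w):
                raise ValidationError("at least one weight must be positive")
            object.__setattr__(self, "weights", w)

    @property
    def knot_spec(self) -> KnotSpec:
        return KnotSpec(self.breaks, self.degree)

    @classmethod
    def for_domain(cls, last_day: float, **kwargs) -> "SmoothingConfig":
        return cls(breaks=default_breaks(last_day), **kwargs)


@dataclass(frozen=True)
class GerminationRecord:
    """One accession's cumulative germination observations.

    ``days`` are strictly increasing nonnegative observation times starting
    at day 0; ``cumulative`` are the corresponding germinated proportions of
    the ``total_seeds`` planted, nondecreasing in time with ``y = 0`` at day
    0.  If day 0 is absent from the input it is prepended with a zero count
    (nothing has germinated before scoring starts).
    """

    accession: str
    days: tuple
    cumulative: tuple
    total_seeds: int

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        cum = np.asarray(self.cumulative, dtype=float)
        if days.shape != cum.shape or days.ndim != 1 or days.size == 0:
            raise ValidationError("days and cumulative must be equal-length 1-D sequences")
        if self.total_seeds <= 0 or int(self.total_seeds) != self.total_seeds:
            raise ValidationError(f"total_seeds must be a positive integer, got {self.total_seeds}")
        if days.size == 0 or days[0] != 0.0:
            # day-zero anchor: nothing germinated at the start of scoring
            days = np.concatenate([[0.0], days])
            cum = np.concatenate([[0.0], cum])
        diffs = np.diff(days)
        if np.any(diffs == 0):
            j = int(np.argmax(diffs == 0))
            raise ValidationError(f"duplicate observation day {days[j]} for {self.accession!r}")
        if np.any(diffs < 0) or days[0] < 0:
            raise ValidationError("days must be strictly increasing and nonnegative")
        if cum[0] != 0.0:
            raise ValidationError("cumulative proportion must be 0 at day 0")
        if np.any(np.diff(cum) < -FEASIBILITY_TOL):
            j = int(np.argmax(np.diff(cum) < -FEASIBILITY_TOL))
            raise ValidationError(
                f"cumulative counts decrease between day {days[j]} and {days[j + 1]} "
                f"for {self.accession!r}"
            )
        if cum.min() < -FEASIBILITY_TOL or cum.max() > 1.0 + FEASIBILITY_TOL:
            raise ValidationError("cumulative proportions must lie in [0, 1]")
        object.__setattr__(self, "days", tuple(days))
        object.__setattr__(self, "cumulative", tuple(cum))
        object.__setattr__(self, "total_seeds", int(self.total_seeds))

    @classmethod
    def from_per_day_counts(
        cls,
        accession: str,
        days: Sequence[float],
        counts: Sequence[float],
        total_seeds: int,
        units: str = "count",
    ) -> "GerminationRecord":
        """Build a record from newly germinated counts per observation day.

        ``units="count"`` interprets the entries as numbers of seeds,
        ``units="percent"`` as percentages of the planted total.
        """
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValidationError("per-day counts must be nonnegative")
        if units == "percent":
            seeds = counts / 100.0 * total_seeds
        elif units == "count":
            seeds = counts
        else:
            raise ValidationError(f"units must be 'count' or 'percent', got {units!r}")
        cum = np.cumsum(seeds) / total_seeds
        return cls(accession, tuple(days), tuple(cum), total_seeds)

    @property
    def final_proportion(self) -> float:
        return self.cumulative[-1]

    def scaled(self, factor: float) -> "GerminationRecord":
        """Record with cumulative proportions multiplied by ``factor`` (for equivariance checks)."""
        cum = tuple(factor * y for y in self.cumulative)
        return GerminationRecord(self.accession, self.days, cum, self.total_seeds)


@dataclass(frozen=True)
class Agdf:
    """A fitted absolute germination distribution function.

    The spline is nonnegative and nondecreasing on its domain by
    construction: the coefficient vector is nonnegative and nondecreasing.
    """

    spec: KnotSpec
    coeffs: tuple
    config: SmoothingConfig
    accession: str = ""

    def __post_init__(self):
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.shape != (self.spec.dimension,):
            raise ValidationError(
                f"expected {self.spec.dimension} coefficients, got {coeffs.size}"
            )
        object.__setattr__(self, "coeffs", tuple(coeffs))

    @property
    def coeff_array(self) -> np.ndarray:
        return np.asarray(self.coeffs, dtype=float)

    def __call__(self, points):
        return eval_agdf(self, points)

    def derivative_values(self, points) -> np.ndarray:
        basis = bspline.eval_basis(self.spec, points, deriv_order=1)
        return basis @ self.coeff_array

    def integral(self, rule: str = "exact") -> float:
        """Area under the spline over [a, b] (the continuous germination index)."""
        if rule == "exact":
            return bspline.integrate_spline(self.coeff_array, self.spec)
        if rule == "trapezoid":
            return bspline.trapezoid_integral(self.coeff_array, self.spec)
        raise ValidationError(f"unknown integration rule {rule!r}")


def _penalty_root(penalty: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD penalty, clipping eigenvalue noise."""
    evals, evecs = np.linalg.eigh(penalty)
    evals = np.clip(evals, 0.0, None)
    return (evecs * np.sqrt(evals)) @ evecs.T


def solve_constrained_ls(
    collocation: np.ndarray,
    penalty: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Minimize the smoothing functional over the monotone-nonnegative cone.

    Returns the B-spline coefficient vector ``b = T g`` where ``g >= 0``
    solves the stacked NNLS problem described in the module docstring.
    """
    collocation = np.asarray(collocation, dtype=float)
    penalty = np.asarray(penalty, dtype=float)
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n, d = collocation.shape
    if penalty.shape != (d, d) or y.shape != (n,) or weights.shape != (n,):
        raise ValidationError("inconsistent dimensions in constrained LS system")

    cumsum_map = np.tril(np.ones((d, d)))
    sqrt_w = np.sqrt(weights)
    top = np.sqrt(alpha) * (sqrt_w[:, None] * collocation) @ cumsum_map
    bottom = np.sqrt(1.0 - alpha) * _penalty_root(penalty) @ cumsum_map
    design = np.vstack([top, bottom])
    target = np.concatenate([np.sqrt(alpha) * sqrt_w * y, np.zeros(d)])

    # tiny Tikhonov term: guarantees a unique minimizer when the stacked
    # system is rank-deficient (e.g. heavily zero-weighted designs)
    ridge = np.sqrt(1e-12 * max(np.abs(design).max() ** 2, 1.0))
    design = np.vstack([design, ridge * np.eye(d)])
    target = np.concatenate([target, np.zeros(d)])

    if not np.all(np.isfinite(design)):
        raise NumericalError("non-finite entries in the stacked smoothing system")
    g, _ = nnls(design, target)
    return cumsum_map @ g


def fit_agdf(record: GerminationRecord, config: SmoothingConfig) -> Agdf:
    """Fit the nonnegative nondecreasing smoothing spline to one record."""
    spec = config.knot_spec
    days = np.asarray(record.days)
    y = np.asarray(record.cumulative)
    scale = max(1.0, abs(spec.a), abs(spec.b))
    if days.min() < spec.a - 1e-9 * scale or days.max() > spec.b + 1e-9 * scale:
        raise DomainError(
            f"observation days of {record.accession!r} fall outside the spline "
            f"domain [{spec.a}, {spec.b}]"
        )
    if config.weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(config.weights, dtype=float)
        if w.shape != y.shape:
            raise ValidationError(
                f"{w.size} weights given for {y.size} observations of {record.accession!r}"
            )
    if np.count_nonzero(w) < 2:
        raise ValidationError("at least 2 observations with positive weight are required")

    collocation = bspline.eval_basis(spec, days)
    penalty = bspline.penalty_gram(spec, config.penalty_order)
    coeffs = solve_constrained_ls(collocation, penalty, y, w, config.alpha)
    return Agdf(spec, tuple(coeffs), config, record.accession)


def eval_agdf(agdf: Agdf, points) -> np.ndarray:
    """Evaluate the fitted spline; raises DomainError outside [a, b]."""
    basis = bspline.eval_basis(agdf.spec, points)
    values = basis @ agdf.coeff_array
    return values if np.ndim(points) else float(values[0])
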