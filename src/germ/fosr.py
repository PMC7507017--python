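"""Function-on-scalar regression of germination curves on scalar indices.

Each smoothed germination curve ``y_i(t)`` (an AGDF) is regressed on an
intercept and one scalar covariate ``x_i`` (a germination index):

    y_i(t) = beta_0(t) + x_i beta_1(t) + eps_i(t)

with functional coefficients estimated by minimizing the integrated squared
error ``SSE(beta) = int (y(t) - X beta(t))^T (y(t) - X beta(t)) dt``.
Because response, coefficients and errors share one B-spline basis, the
functional problem reduces exactly to ordinary least squares on the curves'
coefficient matrix: column nu of the coefficient matrix is regressed on the
design ``X = [1, x]``.

Fit quality is summarized pointwise, R^2(t) = SSR(t) / SST(t), and globally

    R^2_glob = sum_i ||yhat_i - ybar||^2 / sum_i ||y_i - ybar||^2

with exact L2 norms computed through the basis Gram matrix (never grid
sums).  A (near-)constant covariate makes the design singular; such fits
carry a ``singular`` flag and report missing R^2 values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import nan
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bspline
from .bspline import KnotSpec
from .errors import ValidationError
from .indices import INDEX_NAMES, compute_index_set
from .smoothing import Agdf, GerminationRecord, SmoothingConfig, fit_agdf

__all__ = ["FosrFit", "fit_fosr", "r2_pointwise", "r2_global", "compare_indices"]

logger = logging.getLogger("germ")

#: covariate variance below this (after scaling) marks the design singular
SINGULAR_VARIANCE_TOL = 1e-12
#: condition-number ceiling for X^T X
SINGULAR_COND_TOL = 1e12
#: pointwise SST below this marks R^2(t) undefined
POINTWISE_SST_TOL = 1e-12


@dataclass(frozen=True)
class FosrFit:
    """Fitted function-on-scalar regression in a shared spline basis.

    ``coeffs_obs``, ``fitted`` are N x d matrices of curve coefficients;
    ``beta`` is 2 x d (rows: intercept function, slope function).  When
    ``singular`` is set the design was rank-deficient and beta/fitted are
    undefined (NaN).
    """

    spec: KnotSpec
    design: np.ndarray
    coeffs_obs: np.ndarray
    beta: np.ndarray
    fitted: np.ndarray
    singular: bool
    covariate_name: str = ""

    @property
    def residuals(self) -> np.ndarray:
        return self.coeffs_obs - self.fitted

    def beta_splines(self):
        """(intercept, slope) as coefficient vectors in the response basis."""
        return self.beta[0], self.beta[1]


def fit_fosr(curves: Sequence[Agdf], covariate, covariate_name: str = "") -> FosrFit:
    """Regress the curves' B-spline coefficients on [1, x] by least squares."""
    curves = list(curves)
    if len(curves) < 3:
        raise ValidationError(f"at least 3 curves are required, got {len(curves)}")
    spec = curves[0].spec
    for c in curves[1:]:
        if c.spec != spec:
            raise ValidationError("all curves must share one knot sequence and degree")
    x = np.asarray(covariate, dtype=float)
    if x.shape != (len(curves),):
        raise ValidationError("one covariate value per curve is required")
    coeffs = np.vstack([c.coeff_array for c in curves])
    design = np.column_stack([np.ones_like(x), x])

    scale = max(1.0, np.abs(x).max())
    singular = bool(
        np.any(~np.isfinite(x))
        or x.var() / scale**2 < SINGULAR_VARIANCE_TOL
        or np.linalg.cond(design.T @ design) > SINGULAR_COND_TOL
    )
    if singular:
        beta = np.full((2, spec.dimension), nan)
        fitted = np.full_like(coeffs, nan)
        logger.info("singular design for covariate %r; R^2 reported missing", covariate_name)
    else:
        beta, *_ = np.linalg.lstsq(design, coeffs, rcond=None)
        fitted = design @ beta
    return FosrFit(spec, design, coeffs, beta, fitted, singular, covariate_name)


def r2_pointwise(fit: FosrFit, grid) -> np.ndarray:
    """R^2(t) = SSR(t)/SST(t) on a grid; NaN where the curves coincide.

    Values are clipped to [0, 1] for reporting (boundary times where the
    curves nearly coincide can otherwise produce numerically wild ratios).
    """
    if fit.singular:
        raise ValidationError("pointwise R^2 is undefined for a singular fit")
    basis = bspline.eval_basis(fit.spec, grid)
    y = fit.coeffs_obs @ basis.T  # N x npoints
    yhat = fit.fitted @ basis.T
    ybar = y.mean(axis=0)
    sst = ((y - ybar) ** 2).sum(axis=0)
    ssr = ((yhat - ybar) ** 2).sum(axis=0)
    out = np.full(sst.shape, nan)
    ok = sst > POINTWISE_SST_TOL
    out[ok] = np.clip(ssr[ok] / sst[ok], 0.0, 1.0)
    return out


def r2_global(fit: FosrFit) -> float:
    """Global R^2 with exact L2 norms via the basis Gram matrix; NaN if singular."""
    if fit.singular:
        return nan
    gram = bspline.gram_matrix(fit.spec)
    centered_obs = fit.coeffs_obs - fit.coeffs_obs.mean(axis=0)
    centered_fit = fit.fitted - fit.coeffs_obs.mean(axis=0)
    sst = float(np.einsum("id,de,ie->", centered_obs, gram, centered_obs))
    ssr = float(np.einsum("id,de,ie->", centered_fit, gram, centered_fit))
    if sst <= POINTWISE_SST_TOL:
        return nan
    return ssr / sst


def compare_indices(
    records: Sequence[GerminationRecord],
    config: SmoothingConfig,
    index_names: Sequence[str] = INDEX_NAMES,
    drop_zero_germination: bool = False,
    period: Optional[int] = None,
) -> pd.DataFrame:
    """Score each index by the global R^2 of its function-on-scalar fit.

    Fits one AGDF per record, computes every requested index, then runs one
    regression per index with the smoothed curves as functional response.
    ``drop_zero_germination`` removes accessions in which no seed germinated
    before any fitting (the cohort-restriction mode); independently of that,
    records whose covariate is undefined (NaN) are dropped from that index's
    regression only.

    Returns a DataFrame indexed by index name with columns ``r2_glob``
    (NaN when singular or fewer than 3 usable records) and ``n_used``.
    """
    unknown = set(index_names) - set(INDEX_NAMES)
    if unknown:
        raise ValidationError(f"unknown index name(s): {sorted(unknown)}")
    records = list(records)
    if drop_zero_germination:
        records = [r for r in records if r.final_proportion > 0]
    if len(records) < 3:
        raise ValidationError(
            f"at least 3 usable records are required, got {len(records)}"
        )
    agdfs = [fit_agdf(r, config) for r in records]
    sets = [
        compute_index_set(r, config, period=period, agdf=a)
        for r, a in zip(records, agdfs)
    ]
    rows = {}
    for name in index_names:
        x = np.array([getattr(s, name) for s in sets], dtype=float)
        usable = np.isfinite(x)
        if usable.sum() < 3:
            rows[name] = (nan, int(usable.sum()))
            continue
        fit = fit_fosr(
            [a for a, u in zip(agdfs, usable) if u], x[usable], covariate_name=name
        )
        rows[name] = (r2_global(fit), int(usable.sum()))
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["r2_glob", "n_used"])
    frame.index.name = "index"
    return frame
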