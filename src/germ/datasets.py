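"""Embedded fixtures and synthetic germination-data generation.

Two data sources make every stage of the pipeline testable offline:

* the classical hypothetical germination data set of Kader (eight
  scenarios A-H, four seed populations each, 100 seeds scored daily for 10
  days), stored here to the printed one-decimal precision, and
* a stochastic generator producing sigmoid (Hill-type) cumulative
  germination with binomial sampling noise, for property tests and power
  experiments.

An optional loader reconstructs fitted AGDFs from an externally supplied
B-spline coefficient table (the 28-day wild-pea design: quintic basis on
breaks {0, 7, 14, 21, 28}, nine coefficients per accession).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bspline
from .bspline import KnotSpec
from .errors import FormatError, ValidationError
from .smoothing import Agdf, GerminationRecord, SmoothingConfig

__all__ = [
    "HillParams",
    "kader_table2",
    "kader_reference_cgi",
    "simulate_cohort",
    "load_appendix_s1",
]

# Newly germinated seeds (percent of 100 planted) on days 1..10, per
# scenario (A-H) and seed population (sets 1-4).  Values are kept at the
# printed precision; some column totals are 94.8 or 94.5 rather than 95
# because the source table itself carries that rounding.
_KADER_PER_DAY = {
    "A": [
        [0, 0, 0, 15, 80, 0, 0, 0, 0, 0],
        [95, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [10, 20, 65, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 15, 35, 45, 0, 0, 0, 0, 0],
    ],
    "B": [
        [19, 19, 19, 19, 19, 0, 0, 0, 0, 0],
        [23.7, 23.7, 23.7, 23.7, 0, 0, 0, 0, 0, 0],
        [31.6, 31.6, 31.6, 0, 0, 0, 0, 0, 0, 0],
        [47.5, 47.5, 0, 0, 0, 0, 0, 0, 0, 0],
    ],
    "C": [
        [31.6, 31.6, 31.6, 0, 0, 0, 0, 0, 0, 0],
        [25, 25, 25, 0, 0, 0, 0, 0, 0, 0],
        [18.3, 18.3, 18.3, 0, 0, 0, 0, 0, 0, 0],
        [11.6, 11.6, 11.6, 0, 0, 0, 0, 0, 0, 0],
    ],
    "D": [
        [10, 15, 70, 0, 0, 0, 0, 0, 0, 0],
        [70, 15, 10, 0, 0, 0, 0, 0, 0, 0],
        [10, 70, 15, 0, 0, 0, 0, 0, 0, 0],
        [15, 70, 10, 0, 0, 0, 0, 0, 0, 0],
    ],
    "E": [
        [13.5, 13.5, 13.5, 13.5, 13.5, 13.5, 13.5, 0, 0, 0],
        [19, 19, 19, 19, 19, 0, 0, 0, 0, 0],
        [31.6, 31.6, 31.6, 0, 0, 0, 0, 0, 0, 0],
        [95, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    ],
    "F": [
        [0, 0, 0, 0, 0, 0, 0, 31.6, 31.6, 31.6],
        [0, 0, 0, 0, 0, 31.6, 31.6, 31.6, 0, 0],
        [0, 0, 0, 31.6, 31.6, 31.6, 0, 0, 0, 0],
        [0, 31.6, 31.6, 31.6, 0, 0, 0, 0, 0, 0],
    ],
    "G": [
        [9.5, 9.5, 9.5, 9.5, 9.5, 9.5, 9.5, 9.5, 9.5, 9.5],
        [18.7, 18.7, 18.7, 18.7, 0, 0, 0, 0, 0, 0],
        [27.5, 27.5, 0, 0, 0, 0, 0, 0, 0, 0],
        [35, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    ],
    "H": [
        [0, 0, 0, 0, 0, 0, 0, 31.6, 31.6, 31.6],
        [31.6, 31.6, 31.6, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 80, 10, 5],
        [80, 10, 5, 0, 0, 0, 0, 0, 0, 0],
    ],
}

# Published continuous-germination-index values for the 32 hypothetical
# records under the standard 10-day smoothing design (quintic spline, first-
# derivative penalty, alpha = 0.5, breaks {0, 2, 5, 8, 10}); used as a
# cross-study reference in correlation checks.
_KADER_REFERENCE_CGI = {
    "A1": 5.447, "A2": 8.873, "A3": 7.483, "A4": 5.862,
    "B1": 7.076, "B2": 7.525, "B3": 7.979, "B4": 8.440,
    "C1": 7.979, "C2": 6.313, "C3": 4.621, "C4": 2.929,
    "D1": 7.437, "D2": 8.551, "D3": 7.955, "D4": 8.048,
    "E1": 6.109, "E2": 7.076, "E3": 7.979, "E4": 8.873,
    "F1": 1.512, "F2": 3.387, "F3": 5.229, "F4": 7.082,
    "G1": 4.750, "G2": 5.938, "G3": 4.886, "G4": 3.269,
    "H1": 1.512, "H2": 7.979, "H3": 2.203, "H4": 8.690,
}


def kader_table2() -> list:
    """The 32 hypothetical germination records, ids "A1" ... "H4".

    Each record covers days 0-10 (day-0 zero anchor prepended) with 100
    planted seeds and per-day percentages exactly as printed.
    """
    days = list(range(1, 11))
    records = []
    for scenario in "ABCDEFGH":
        for set_no, per_day in enumerate(_KADER_PER_DAY[scenario], start=1):
            records.append(
                GerminationRecord.from_per_day_counts(
                    f"{scenario}{set_no}", days, per_day, total_seeds=100, units="percent"
                )
            )
    return records


def kader_reference_cgi() -> dict:
    """Published CGI reference values for the 32 records (copy)."""
    return dict(_KADER_REFERENCE_CGI)


@dataclass(frozen=True)
class HillParams:
    """Parameters of one simulated accession's underlying Hill curve.

    The expected cumulative germinated proportion at day ``t`` is
    ``p(t) = c * t^a / (b^a + t^a)``: ``c`` is the germination ceiling
    (viable fraction), ``b`` the half-time in days (``p(b) = c/2``) and
    ``a > 1`` the sigmoid steepness.
    """

    ceiling: float
    half_time: float
    shape: float
    total_seeds: int = 100
    accession: str = ""

    def __post_init__(self):
        if not 0.0 <= self.ceiling <= 1.0:
            raise ValidationError(f"ceiling must be in [0, 1], got {self.ceiling}")
        if self.ceiling > 0 and self.half_time <= 0:
            raise ValidationError(f"half_time must be positive, got {self.half_time}")
        if self.shape <= 1:
            raise ValidationError(f"shape must exceed 1, got {self.shape}")
        if self.total_seeds <= 0:
            raise ValidationError("total_seeds must be positive")

    def expected_proportion(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = self.ceiling * t**self.shape / (self.half_time**self.shape + t**self.shape)
        return np.where(t <= 0, 0.0, p)


def simulate_cohort(
    params: Sequence[HillParams],
    days: Sequence[int],
    seed: int,
    noise: bool = True,
) -> list:
    """Draw one GerminationRecord per parameter set.

    Each seed's germination day follows the (defective) distribution with
    CDF ``p(t)``; counts are drawn day by day as binomial increments from
    the not-yet-germinated pool with the conditional hazard
    ``(p(t) - p(t-1)) / (1 - p(t-1))``, which guarantees a nondecreasing
    cumulative record.  ``noise=False`` returns the rounded expected
    cumulative counts instead (a noiseless discretization of the curve).
    """
    days = np.asarray(days, dtype=float)
    if days.size == 0 or days[0] < 1:
        raise ValidationError("observation days must start at day 1 or later")
    if np.any(np.diff(days) <= 0):
        raise ValidationError("observation days must be strictly increasing")
    rng = np.random.default_rng(seed)
    records = []
    for i, par in enumerate(params):
        name = par.accession or f"sim{i + 1}"
        p = par.expected_proportion(days)
        if not noise:
            cum = np.round(p * par.total_seeds) / par.total_seeds
        else:
            germinated = 0
            prev_p = 0.0
            counts = np.zeros(days.size, dtype=int)
            for j, pj in enumerate(p):
                hazard = 0.0 if prev_p >= 1.0 else (pj - prev_p) / (1.0 - prev_p)
                hazard = min(max(hazard, 0.0), 1.0)
                counts[j] = rng.binomial(par.total_seeds - germinated, hazard)
                germinated += counts[j]
                prev_p = pj
            cum = np.cumsum(counts) / par.total_seeds
        records.append(GerminationRecord(name, tuple(days), tuple(cum), par.total_seeds))
    return records


def load_appendix_s1(
    path,
    breaks: Sequence[float] = (0.0, 7.0, 14.0, 21.0, 28.0),
    degree: int = 5,
    cgi_tolerance: float = 1e-3,
) -> tuple:
    """Load a supplementary B-spline coefficient table as fitted AGDFs.

    Expects a CSV with an accession column, exactly ``dimension`` coefficient
    columns (named ``b1..b9`` or detected as the first numeric block), and
    optionally a ``CGI`` column; extra metadata columns are tolerated.
    Returns ``(agdfs, cgi_values)`` where ``cgi_values`` are recomputed from
    the coefficients.  If the file carries a CGI column it is checked
    against the recomputed integrals.
    """
    spec = KnotSpec(tuple(breaks), degree)
    dim = spec.dimension
    frame = pd.read_csv(path)
    cols = list(frame.columns)
    named = [c for c in cols if c.lower() in {f"b{i}" for i in range(1, dim + 1)}]
    if len(named) == dim:
        coeff_cols = sorted(named, key=lambda c: int(c[1:]))
    else:
        numeric = [c for c in cols if pd.api.types.is_numeric_dtype(frame[c])]
        numeric = [c for c in numeric if c.lower() != "cgi"]
        if len(numeric) < dim:
            raise FormatError(
                f"need {dim} coefficient columns for the {dim}-dimensional basis, "
                f"found {len(numeric)} numeric columns"
            )
        coeff_cols = numeric[:dim]
    acc_col = cols[0] if not pd.api.types.is_numeric_dtype(frame[cols[0]]) else None
    config = SmoothingConfig(breaks=tuple(breaks), degree=degree)
    agdfs, cgis = [], []
    for i, row in frame.iterrows():
        coeffs = row[coeff_cols].to_numpy(dtype=float)
        if np.any(coeffs < -1e-8) or np.any(np.diff(coeffs) < -1e-8):
            raise FormatError(
                f"row {i}: coefficients are not nonnegative and nondecreasing"
            )
        name = str(row[acc_col]) if acc_col else f"acc{i + 1}"
        agdf = Agdf(spec, tuple(coeffs), config, name)
        agdfs.append(agdf)
        cgis.append(bspline.integrate_spline(coeffs, spec))
    cgis = np.asarray(cgis)
    cgi_col = next((c for c in cols if c.lower() == "cgi"), None)
    if cgi_col is not None:
        stated = frame[cgi_col].to_numpy(dtype=float)
        if np.max(np.abs(stated - cgis)) > cgi_tolerance:
            raise FormatError(
                "stated CGI column disagrees with the integral of the coefficients"
            )
    return agdfs, cgis
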