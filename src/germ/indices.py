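"""Germination indices: five classical discrete measures plus the CGI.

Discrete measures operate on the per-day germinated counts ``n_i`` at days
``t_i`` (first differences of the cumulative record, in seed units):

* TG   -- total germination, the final cumulative proportion in [0, 1].
* MGT  -- mean germination time, ``sum(n_i t_i) / sum(n_i)`` (days).
* CVG  -- coefficient of velocity, ``100 * sum(n_i) / sum(n_i t_i)``
          (percent per day); higher means faster.
* GI   -- germination index, ``sum((T - t_i + 1) n_i)`` over a scoring
          period of T days: seeds germinating on day 1 carry weight T,
          those on the last day weight 1.
* LT50 -- first observation day at which the cumulative count reaches half
          of its final level (optionally linearly interpolated).

The continuous germination index (CGI) is the area under the fitted AGDF,
``CGI = int_a^b s(t) dt``, in days x proportion; it is bounded by the
domain length ``b - a``.

When nothing germinates, LT50, MGT and CVG are undefined and reported as
NaN (never coerced to 0); GI and CGI are genuinely 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan
from typing import Optional

import numpy as np

from .errors import ValidationError
from .smoothing import Agdf, GerminationRecord, SmoothingConfig, fit_agdf

__all__ = [
    "IndexSet",
    "per_day_counts",
    "total_germination",
    "mean_germination_time",
    "coefficient_of_velocity",
    "germination_index",
    "lt50",
    "cgi",
    "compute_index_set",
]

INDEX_NAMES = ("lt50", "tg", "mgt", "cvg", "gi", "cgi")


@dataclass(frozen=True)
class IndexSet:
    """The six indices for one accession; NaN marks an undefined value."""

    accession: str
    lt50: float
    tg: float
    mgt: float
    cvg: float
    gi: float
    cgi: float

    def as_dict(self) -> dict:
        return {
            "accession": self.accession,
            "lt50": self.lt50,
            "tg": self.tg,
            "mgt": self.mgt,
            "cvg": self.cvg,
            "gi": self.gi,
            "cgi": self.cgi,
        }


def per_day_counts(record: GerminationRecord):
    """Newly germinated seeds per observation day (day 0 excluded).

    Returns ``(days, counts)`` in seed units; counts are the first
    differences of the cumulative record scaled by the planted total.
    """
    cum = np.asarray(record.cumulative)
    counts = np.diff(cum) * record.total_seeds
    counts = np.where(np.abs(counts) < 1e-12, 0.0, counts)
    if np.any(counts < 0):
        raise ValidationError(f"decreasing cumulative counts in {record.accession!r}")
    return np.asarray(record.days[1:]), counts


def total_germination(record: GerminationRecord) -> float:
    """Final germinated proportion of planted seeds (TG, in [0, 1])."""
    return float(record.final_proportion)


def mean_germination_time(counts, days) -> float:
    """Count-weighted mean day of germination (MGT, days); NaN if no germination."""
    counts = np.asarray(counts, dtype=float)
    days = np.asarray(days, dtype=float)
    total = counts.sum()
    if total <= 0:
        return nan
    return float((counts * days).sum() / total)


def coefficient_of_velocity(counts, days) -> float:
    """CVG = 100 * sum(n_i) / sum(n_i t_i), percent per day; NaN if no germination."""
    counts = np.asarray(counts, dtype=float)
    days = np.asarray(days, dtype=float)
    total = counts.sum()
    if total <= 0:
        return nan
    return float(100.0 * total / (counts * days).sum())


def germination_index(counts, days, period: int) -> float:
    """GI with linearly decreasing weights T - t + 1 over a T-day period."""
    counts = np.asarray(counts, dtype=float)
    days = np.asarray(days, dtype=float)
    if np.any(days[counts > 0] > period):
        raise ValidationError(
            f"germination observed after the scoring period of {period} days"
        )
    return float(((period - days + 1) * counts).sum())


def lt50(record: GerminationRecord, interpolate: bool = False) -> float:
    """Time to half of the final germination level (days); NaN if nothing germinated.

    Default: the first observation day whose cumulative count reaches half
    the final level, matching how the measure is scored on a daily grid.
    ``interpolate=True`` instead interpolates linearly between observations.
    """
    cum = np.asarray(record.cumulative)
    days = np.asarray(record.days)
    final = cum[-1]
    if final <= 0:
        return nan
    half = 0.5 * final
    idx = int(np.argmax(cum >= half - 1e-12))
    if not interpolate:
        return float(days[idx])
    if cum[idx] <= half or idx == 0:
        return float(days[idx])
    t0, t1 = days[idx - 1], days[idx]
    y0, y1 = cum[idx - 1], cum[idx]
    return float(t0 + (half - y0) / (y1 - y0) * (t1 - t0))


def cgi(agdf: Agdf, rule: str = "exact") -> float:
    """Continuous germination index: area under the AGDF over its domain."""
    return agdf.integral(rule)


def compute_index_set(
    record: GerminationRecord,
    config: SmoothingConfig,
    period: Optional[int] = None,
    agdf: Optional[Agdf] = None,
) -> IndexSet:
    """All six indices for one accession.

    ``period`` defaults to the last observation day; a pre-fitted AGDF can
    be passed to avoid refitting in batch pipelines.
    """
    days, counts = per_day_counts(record)
    if period is None:
        period = int(round(record.days[-1]))
    if agdf is None:
        agdf = fit_agdf(record, config)
    return IndexSet(
        accession=record.accession,
        lt50=lt50(record),
        tg=total_germination(record),
        mgt=mean_germination_time(counts, days),
        cvg=coefficient_of_velocity(counts, days),
        gi=germination_index(counts, days, period),
        cgi=cgi(agdf),
    )
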