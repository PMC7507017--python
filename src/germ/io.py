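"""Tabular readers/writers, configuration handling and the batch pipeline.

The interchange format is a wide CSV: one row per accession with columns
``accession, total_seeds, day_1 ... day_n``.  Counts may be newly
germinated per day or cumulative, in seeds or percent of the planted total;
the caller declares which.  Missing cells are rejected rather than imputed
(the smoothing model assumes scoring on a fixed day grid), and cumulative
rows must be nondecreasing.

Floats are written with ``%.6g`` so repeated runs produce byte-identical
output.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .fosr import compare_indices
from .indices import INDEX_NAMES, compute_index_set
from .smoothing import Agdf, GerminationRecord, SmoothingConfig, default_breaks, fit_agdf

__all__ = [
    "read_records",
    "write_records",
    "load_config",
    "write_splines",
    "write_index_table",
    "write_r2_table",
    "run_pipeline",
    "PipelineResult",
    "FLOAT_FORMAT",
]

logger = logging.getLogger("germ")

FLOAT_FORMAT = "%.6g"


def configure_logging(quiet: bool = False) -> None:
    """Stage logging to stderr; ``quiet`` suppresses it for scripted use."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[germ] %(message)s"))
    logger.handlers = [handler]
    logger.setLevel(logging.WARNING if quiet else logging.INFO)


def read_records(path, mode: str = "per-day", units: str = "percent") -> list:
    """Read a wide CSV into validated GerminationRecords.

    ``mode`` declares whether day columns hold newly germinated counts
    ("per-day") or running totals ("cumulative"); ``units`` is "count"
    (seeds) or "percent" (of total_seeds).
    """
    if mode not in ("per-day", "cumulative"):
        raise ValidationError(f"mode must be 'per-day' or 'cumulative', got {mode!r}")
    frame = pd.read_csv(path)
    required = {"accession", "total_seeds"}
    if not required.issubset(frame.columns):
        raise FormatError(f"missing required column(s): {sorted(required - set(frame.columns))}")
    day_cols = [c for c in frame.columns if c.startswith("day_")]
    if not day_cols:
        raise FormatError("no day_<n> columns found")
    try:
        days = sorted((int(c.split("_", 1)[1]) for c in day_cols))
    except ValueError as exc:
        raise FormatError(f"malformed day column name: {exc}") from exc
    day_cols = [f"day_{d}" for d in days]
    records = []
    for i, row in frame.iterrows():
        values = row[day_cols].to_numpy(dtype=float)
        if np.any(~np.isfinite(values)):
            j = int(np.argmax(~np.isfinite(values)))
            raise FormatError(
                f"missing value in row {row['accession']!r}, column {day_cols[j]}"
            )
        total = int(row["total_seeds"])
        if mode == "cumulative":
            if np.any(np.diff(values) < 0):
                j = int(np.argmax(np.diff(values) < 0))
                raise FormatError(
                    f"cumulative counts decrease in row {row['accession']!r} "
                    f"between {day_cols[j]} and {day_cols[j + 1]}"
                )
            cum = values / 100.0 if units == "percent" else values / total
            records.append(
                GerminationRecord(str(row["accession"]), tuple(days), tuple(cum), total)
            )
        else:
            records.append(
                GerminationRecord.from_per_day_counts(
                    str(row["accession"]), days, values, total, units=units
                )
            )
    return records


def write_records(records: Sequence[GerminationRecord], path, mode: str = "per-day") -> None:
    """Write records to the wide CSV format (percent units)."""
    rows = []
    for rec in records:
        cum = np.asarray(rec.cumulative[1:]) * 100.0
        values = np.concatenate([[cum[0]], np.diff(cum)]) if mode == "per-day" else cum
        row = {"accession": rec.accession, "total_seeds": rec.total_seeds}
        row.update({f"day_{int(d)}": v for d, v in zip(rec.days[1:], values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def load_config(path=None, last_day: Optional[float] = None, **overrides) -> SmoothingConfig:
    """Build a SmoothingConfig from a YAML/JSON file and/or overrides.

    Recognized keys: degree, penalty_order, breaks, alpha, weights.  When no
    breaks are given they default to the standard design for ``last_day``.
    """
    payload = {}
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        payload = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if not isinstance(payload, dict):
            raise FormatError(f"config file {path} must contain a mapping")
    payload.update({k: v for k, v in overrides.items() if v is not None})
    if "breaks" not in payload:
        if last_day is None:
            raise ValidationError("no breaks given and no observation horizon to infer them from")
        payload["breaks"] = default_breaks(last_day)
    known = {"degree", "penalty_order", "breaks", "alpha", "weights"}
    unknown = set(payload) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    if "breaks" in payload:
        payload["breaks"] = tuple(payload["breaks"])
    if payload.get("weights") is not None:
        payload["weights"] = tuple(payload["weights"])
    return SmoothingConfig(**payload)


def write_splines(agdfs: Sequence[Agdf], path) -> None:
    """One row per accession: degree, semicolon-joined breaks, b1..bd, cgi."""
    rows = []
    for a in agdfs:
        row = {
            "accession": a.accession,
            "degree": a.spec.degree,
            "breaks": ";".join(FLOAT_FORMAT % x for x in a.spec.breaks),
        }
        row.update({f"b{i + 1}": c for i, c in enumerate(a.coeffs)})
        row["cgi"] = a.integral()
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_index_table(index_sets, path) -> None:
    """Table-of-indices CSV; undefined values become empty fields."""
    frame = pd.DataFrame([s.as_dict() for s in index_sets])
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="")


def write_r2_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, float_format=FLOAT_FORMAT, na_rep="NA")


@dataclass
class PipelineResult:
    agdfs: list
    index_table: pd.DataFrame
    r2_table: Optional[pd.DataFrame]


def run_pipeline(
    records: Sequence[GerminationRecord],
    config: SmoothingConfig,
    index_names: Sequence[str] = INDEX_NAMES,
    drop_zero_germination: bool = False,
    period: Optional[int] = None,
) -> PipelineResult:
    """Smooth every record, compute all indices, and (N >= 3) run the
    index-comparison regressions.

    Deterministic given inputs and configuration.  The regression stage is
    skipped with a warning when fewer than 3 records are available.
    """
    records = list(records)
    if not records:
        raise ValidationError("at least one record is required")
    t0 = time.perf_counter()
    agdfs = [fit_agdf(r, config) for r in records]
    logger.info("smoothed %d records in %.2fs", len(records), time.perf_counter() - t0)
    t0 = time.perf_counter()
    sets = [
        compute_index_set(r, config, period=period, agdf=a)
        for r, a in zip(records, agdfs)
    ]
    index_table = pd.DataFrame([s.as_dict() for s in sets])
    logger.info("computed indices in %.2fs", time.perf_counter() - t0)
    usable = [r for r in records if not drop_zero_germination or r.final_proportion > 0]
    if len(usable) < 3:
        logger.warning("fewer than 3 records; regression stage skipped")
        r2 = None
    else:
        t0 = time.perf_counter()
        r2 = compare_indices(
            records,
            config,
            index_names=index_names,
            drop_zero_germination=drop_zero_germination,
            period=period,
        )
        logger.info("index comparison in %.2fs", time.perf_counter() - t0)
    return PipelineResult(agdfs, index_table, r2)
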