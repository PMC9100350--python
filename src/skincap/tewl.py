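"""Repeat-measurement statistics for TEWL series.

Trans-epidermal water loss (TEWL, g·m⁻²·h⁻¹) is measured as a handful of
replicate probe readings per site and timepoint.  This module provides the
descriptive statistics the analysis rests on: mean, sample SD, the
coefficient of variation (the instrument-repeatability metric), before/after
changes, and a per-group study report.  No hypothesis testing: with n = 5
replicates per group the analysis is deliberately descriptive, and raw
replicates remain available for external testing.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .dataio import MeasurementSeries

__all__ = [
    "summarize",
    "coefficient_of_variation",
    "tewl_change",
    "site_report",
]

logger = logging.getLogger(__name__)


def summarize(series: MeasurementSeries) -> tuple[float, float, int]:
    """Arithmetic mean, sample SD (n-1 denominator; 0 when n = 1), and n."""
    vals = series.as_array()
    n = vals.size
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def coefficient_of_variation(series: MeasurementSeries) -> float:
    """CV in percent: 100 * sample SD / mean.

    Requires at least two replicates and a positive mean.
    """
    mean, sd, n = summarize(series)
    if n < 2:
        raise ValueError("CV undefined for fewer than 2 replicates")
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return 100.0 * sd / mean


def tewl_change(
    before: MeasurementSeries, after: MeasurementSeries
) -> tuple[float, float]:
    """Change of the mean reading: (delta, delta in % of the before mean)."""
    mean_b, _, _ = summarize(before)
    mean_a, _, _ = summarize(after)
    if mean_b <= 0:
        raise ValueError("before-mean must be positive")
    delta = mean_a - mean_b
    return delta, 100.0 * delta / mean_b


def site_report(
    series: Iterable[MeasurementSeries], baseline: str = "before"
) -> pd.DataFrame:
    """One row per (site, timepoint, instrument): mean, sd, cv, delta, delta_pct.

    Deltas are relative to the same site/instrument at the baseline timepoint;
    the baseline rows have delta 0.  A group whose baseline is missing gets
    NaN deltas and a logged warning.  CV is NaN where undefined (n < 2).
    """
    series = list(series)
    by_key = {(s.site_id, s.timepoint, s.instrument): s for s in series}
    rows = []
    for s in series:
        mean, sd, n = summarize(s)
        cv = 100.0 * sd / mean if (n >= 2 and mean > 0) else np.nan
        base = by_key.get((s.site_id, baseline, s.instrument))
        if base is None:
            logger.warning(
                "site %s / instrument %s: no %r baseline series; deltas undefined",
                s.site_id, s.instrument, baseline,
            )
            delta = delta_pct = np.nan
        else:
            delta, delta_pct = tewl_change(base, s)
        rows.append(
            dict(
                site_id=s.site_id,
                timepoint=s.timepoint,
                instrument=s.instrument,
                n=n,
                mean=mean,
                sd=sd,
                cv=cv,
                delta=delta,
                delta_pct=delta_pct,
            )
        )
    return pd.DataFrame(rows)
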