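"""Median-relative ratio statistics for country league tables.

A country's burden or exposure metric in a given year is divided by the
median of all countries in that same year (the country is included in its
own reference median). The ratio at two anchor years gives a change

    change = (ratio_start - ratio_end) / ratio_start

which is positive exactly when the country reduced its own metric by more
than the median country did — i.e. when it "kept pace" with the region.
The four named instances are:

* DARR — DALY rate ratio (air-pollution-attributable DALY rate)
* PMR  — ambient PM2.5 concentration ratio
* YRR  — YLL rate ratio
* DRR  — death rate ratio

``classify_panel`` applies the calculation to a tidy country-year panel and
labels each country positive / neutral / negative, with a small tolerance
around zero so that countries whose ratios are equal at printed precision
in both years are reported as neutral rather than spuriously signed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError, DataCompletenessError, DomainError

__all__ = [
    "RatioSet",
    "reference_median",
    "ratio_to_median",
    "ratio_change",
    "classify_change",
    "classify_panel",
    "DEFAULT_NEUTRAL_TOLERANCE",
]

#: |change| at or below this is classified neutral. Changes are printed as
#: percents with one decimal, so 5e-3 on the fraction scale is half a
#: printed unit.
DEFAULT_NEUTRAL_TOLERANCE = 5e-3


@dataclass(frozen=True)
class RatioSet:
    """One country's median-relative ratios at the two anchor years."""

    country: str
    metric: str
    ratio_start: float
    ratio_end: float
    change: float
    classification: str  # positive | neutral | negative


def reference_median(values) -> float:
    """Median of the reference set (mean of the two middle order statistics
    for even n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ArgumentError("reference set must be non-empty")
    return float(np.median(arr))


def ratio_to_median(country_value: float, all_values) -> float:
    """Ratio of one country's value to the median of all countries.

    The country's own value must be a member of ``all_values``; the country
    is not excluded from its own reference median.
    """
    arr = np.asarray(all_values, dtype=float)
    if not np.any(np.isclose(arr, country_value, rtol=1e-12, atol=0.0)):
        raise ArgumentError("country_value must be a member of all_values")
    med = reference_median(arr)
    if med == 0:
        raise DomainError("reference median is zero")
    return country_value / med


def ratio_change(ratio_start: float, ratio_end: float) -> float:
    """Relative decline of the ratio between the anchor years.

    Positive means the country out-reduced the reference median; negative
    means it fell behind the median's pace even if its own raw metric
    improved.
    """
    if ratio_start == 0:
        raise DomainError("ratio_start must be non-zero")
    return (ratio_start - ratio_end) / ratio_start


def classify_change(change: float, tolerance: float = DEFAULT_NEUTRAL_TOLERANCE) -> str:
    if abs(change) <= tolerance:
        return "neutral"
    return "positive" if change > 0 else "negative"


def classify_panel(
    panel: pd.DataFrame,
    metric: str = "daly_rate",
    year_start: int = 1990,
    year_end: int = 2019,
    cause: str = "all_cause",
    pollutant: str = "all",
    tolerance: float = DEFAULT_NEUTRAL_TOLERANCE,
) -> pd.DataFrame:
    """Median-relative ratios and their change for every country in a panel.

    Parameters
    ----------
    panel
        Tidy country-year panel (one row per country, year, cause, pollutant)
        as produced by :func:`airburden.synthetic.generate_panel` or read by
        :func:`airburden.panelio.read_panel`.
    metric
        Column to compare (``daly_rate`` gives DARR, ``apm25`` PMR,
        ``yll_rate`` YRR, ``death_rate`` DRR).
    cause, pollutant
        Slice used for burden metrics; exposure metrics such as ``apm25`` are
        constant across these tags, so any slice gives the same answer.

    Returns
    -------
    DataFrame with columns country, metric, ratio_start, ratio_end, change,
    classification — one row per country, sorted by country.
    """
    if metric not in panel.columns:
        raise ArgumentError(f"metric column {metric!r} not in panel")
    sub = panel[(panel["cause"] == cause) & (panel["pollutant"] == pollutant)]
    slices = {}
    for year in (year_start, year_end):
        s = sub[sub["year"] == year].set_index("country")[metric]
        slices[year] = s
    countries = sorted(set(slices[year_start].index) | set(slices[year_end].index))
    missing = [
        c
        for c in countries
        if c not in slices[year_start].index or c not in slices[year_end].index
    ]
    if missing:
        raise DataCompletenessError(
            f"countries missing an anchor year ({year_start} or {year_end}): {missing}"
        )
    if any((slices[y] <= 0).any() for y in slices):
        raise DomainError(f"metric {metric!r} must be positive in both anchor years")

    rows = []
    for year in (year_start, year_end):
        values = slices[year].loc[countries].to_numpy(dtype=float)
        med = reference_median(values)
        slices[year] = slices[year].loc[countries] / med
    for c in countries:
        r0 = float(slices[year_start][c])
        r1 = float(slices[year_end][c])
        change = ratio_change(r0, r1)
        rows.append(
            RatioSet(c, metric, r0, r1, change, classify_change(change, tolerance))
        )
    return pd.DataFrame(rows)
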