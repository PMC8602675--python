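"""SDI and GNI bracket assignment and per-group median/IQR summaries.

Default schemes mirror the brackets used for European cross-country burden
comparisons:

* SDI (socio-demographic index, 0-1): low < 0.750, medium 0.750-0.849,
  high >= 0.850. The printed brackets ("< 0.749", "> 0.850") leave tiny gaps
  at the boundaries; the implementation closes them with half-open intervals
  low [0, 0.750), medium [0.750, 0.850), high [0.850, 1].
* GNI per capita (Atlas US$): the two World Bank middle-income bands are
  merged into one bracket, and the high-income band is split three ways —
  merged middle [1,036, 12,536), lower high [12,536, 36,767), moderate high
  [36,767, 60,998), very high >= 60,998.

Quartiles default to Tukey's median-of-halves with the median excluded from
either half for odd n, so {1,2,3,4,5} has IQR (1.5, 4.5); the rule is
configurable because published tables rarely state their convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError, DomainError

__all__ = [
    "GroupScheme",
    "GroupSummary",
    "sdi_scheme",
    "gni_scheme",
    "assign_group",
    "group_summary",
    "tukey_quartiles",
    "fold_ratio",
    "group_values",
]


@dataclass(frozen=True)
class GroupScheme:
    """Ordered brackets over a value range.

    ``edges`` has one more element than ``labels``; bracket i covers
    [edges[i], edges[i+1]), except the terminal bracket which includes its
    upper edge.
    """

    name: str
    labels: tuple[str, ...]
    edges: tuple[float, ...]

    def __post_init__(self):
        if len(self.edges) != len(self.labels) + 1:
            raise ArgumentError("edges must have exactly one more element than labels")
        if any(nxt <= prev for prev, nxt in zip(self.edges, self.edges[1:])):
            raise ArgumentError("edges must be strictly increasing")
        if len(set(self.labels)) != len(self.labels):
            raise ArgumentError("labels must be unique")

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "labels": list(self.labels), "edges": list(self.edges)},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroupScheme":
        d = json.loads(text)
        unknown = set(d) - {"name", "labels", "edges"}
        if unknown:
            raise ArgumentError(f"unknown scheme keys: {sorted(unknown)}")
        return cls(d["name"], tuple(d["labels"]), tuple(float(e) for e in d["edges"]))


@dataclass(frozen=True)
class GroupSummary:
    """Median and interquartile range of one bracket (NaN when n < 1)."""

    bracket: str
    n: int
    median: float
    q1: float
    q3: float
    measure: str


def sdi_scheme() -> GroupScheme:
    return GroupScheme("sdi", ("low", "medium", "high"), (0.0, 0.750, 0.850, 1.0))


def gni_scheme() -> GroupScheme:
    return GroupScheme(
        "gni",
        ("merged_middle", "lower_high", "moderate_high", "very_high"),
        (1036.0, 12536.0, 36767.0, 60998.0, math.inf),
    )


def assign_group(value: float, scheme: GroupScheme) -> str:
    """Bracket label for one value; values outside the covered range (or NaN,
    e.g. a country with no published GNI) raise a DomainError."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise DomainError(f"missing value cannot be assigned to a {scheme.name} bracket")
    last = scheme.edges[-1]
    if value < scheme.edges[0] or (value > last) or (value == last and math.isinf(last)):
        raise DomainError(
            f"value {value} outside {scheme.name} coverage [{scheme.edges[0]}, {last}]"
        )
    if value == last:
        return scheme.labels[-1]
    idx = int(np.searchsorted(np.asarray(scheme.edges), value, side="right")) - 1
    return scheme.labels[idx]


def tukey_quartiles(values) -> tuple[float, float]:
    """Median-of-halves quartiles, excluding the overall median from each
    half when n is odd."""
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ArgumentError("cannot take quartiles of an empty set")
    half = n // 2
    lower = arr[:half]
    upper = arr[-half:] if half else arr
    if half == 0:  # single observation
        return float(arr[0]), float(arr[0])
    return float(np.median(lower)), float(np.median(upper))


def fold_ratio(low_median: float, high_median: float) -> float:
    """How many times higher the low bracket's median is than the high
    bracket's (e.g. "11-fold higher DALY rate")."""
    if high_median <= 0:
        raise DomainError("high bracket median must be positive")
    return low_median / high_median


def group_summary(
    panel: pd.DataFrame,
    scheme: GroupScheme,
    measure: str = "daly_rate",
    cause: str = "ihd",
    pollutant: str = "all",
    year: int = 2019,
    quartiles=tukey_quartiles,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-bracket n, median and IQR of one measure in one year.

    Countries with a missing grouping value (NaN SDI or GNI) are excluded
    from the summaries and returned in the second element so the exclusion
    is auditable, mirroring analyses run on "39 of 43" countries. Empty
    brackets are reported with n = 0 and NaN summaries, never dropped.
    """
    value_col = scheme.name
    if value_col not in panel.columns or measure not in panel.columns:
        raise ArgumentError(f"panel must carry columns {value_col!r} and {measure!r}")
    sub = panel[
        (panel["year"] == year)
        & (panel["cause"] == cause)
        & (panel["pollutant"] == pollutant)
    ][["country", value_col, measure]].drop_duplicates("country")
    excluded = sorted(sub.loc[sub[value_col].isna(), "country"])
    sub = sub.dropna(subset=[value_col])
    assigned = sub[value_col].map(lambda v: assign_group(float(v), scheme))
    rows = []
    for label in scheme.labels:
        vals = sub.loc[assigned == label, measure].to_numpy(dtype=float)
        if vals.size == 0:
            rows.append(GroupSummary(label, 0, math.nan, math.nan, math.nan, measure))
        else:
            q1, q3 = quartiles(vals)
            rows.append(
                GroupSummary(label, int(vals.size), float(np.median(vals)), q1, q3, measure)
            )
    return pd.DataFrame(rows), excluded


def group_values(
    panel: pd.DataFrame,
    scheme: GroupScheme,
    measure: str = "daly_rate",
    cause: str = "ihd",
    pollutant: str = "all",
    year: int = 2019,
) -> dict[str, np.ndarray]:
    """Raw per-bracket value arrays (one value per country), for feeding the
    Kruskal-Wallis / Dunn tests; empty brackets are omitted."""
    sub = panel[
        (panel["year"] == year)
        & (panel["cause"] == cause)
        & (panel["pollutant"] == pollutant)
    ][["country", scheme.name, measure]].drop_duplicates("country")
    sub = sub.dropna(subset=[scheme.name])
    assigned = sub[scheme.name].map(lambda v: assign_group(float(v), scheme))
    out = {}
    for label in scheme.labels:
        vals = sub.loc[assigned == label, measure].to_numpy(dtype=float)
        if vals.size:
            out[label] = vals
    return out
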