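"""Population attributable fraction (PAF) and attributable-burden arithmetic.

The comparative-risk-assessment chain implemented here is the standard one
for a continuous environmental exposure such as ambient PM2.5:

1. the population's exposure is summarised as a discrete distribution
   (proportion of population per exposure bin);
2. a relative-risk curve, normalised to RR = 1 at the theoretical minimum
   risk exposure level (TMREL), is evaluated at each bin midpoint;
3. PAF = (sum_i p_i RR_i - 1) / (sum_i p_i RR_i);
4. attributable burden = PAF x total outcome (deaths, YLL or DALYs), which
   can then be expressed as a rate per 100,000 population and
   age-standardised against a fixed standard population.

Uncertainty intervals are deliberately not computed: draw-level UI machinery
belongs to the upstream burden studies, not to this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ArgumentError, DomainError

__all__ = [
    "ExposureDistribution",
    "RelativeRiskCurve",
    "StandardPopulation",
    "BurdenResult",
    "compute_paf",
    "attributable_burden",
    "rate_per_100k",
    "age_standardise",
    "percent_change",
    "share_of_total",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of printed
    epidemiological tables), e.g. ``round_half_away(2.5) == 3``.

    Used only when comparing full-precision results against printed numbers;
    all computation stays at full precision.
    """
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ExposureDistribution:
    """Binned population exposure: ``proportion[i]`` of the population sits at
    exposure ``bin_mid[i]`` (ug/m3 for particulate metrics)."""

    bin_mid: np.ndarray
    proportion: np.ndarray

    def __post_init__(self):
        mid = np.asarray(self.bin_mid, dtype=float)
        prop = np.asarray(self.proportion, dtype=float)
        object.__setattr__(self, "bin_mid", mid)
        object.__setattr__(self, "proportion", prop)
        if mid.ndim != 1 or mid.size == 0 or mid.shape != prop.shape:
            raise ArgumentError("bin_mid and proportion must be equal-length, non-empty 1-d arrays")
        if np.any(mid < 0) or np.any(np.diff(mid) <= 0):
            raise ArgumentError("bin_mid must be non-negative and strictly increasing")
        if np.any(prop < 0) or abs(prop.sum() - 1.0) > 1e-9:
            raise ArgumentError("proportion must be non-negative and sum to 1 within 1e-9")


@dataclass(frozen=True)
class RelativeRiskCurve:
    """Piecewise-linear relative-risk curve with a point TMREL.

    Between knots the curve is linearly interpolated; beyond the end knots it
    is extrapolated flat. Evaluation normalises the curve so RR(tmrel) = 1,
    and exposure below the TMREL carries no excess risk (RR = 1).
    """

    knot_exposure: np.ndarray
    knot_rr: np.ndarray
    tmrel: float

    def __post_init__(self):
        x = np.asarray(self.knot_exposure, dtype=float)
        r = np.asarray(self.knot_rr, dtype=float)
        object.__setattr__(self, "knot_exposure", x)
        object.__setattr__(self, "knot_rr", r)
        if x.ndim != 1 or x.size == 0 or x.shape != r.shape:
            raise ArgumentError("knot_exposure and knot_rr must be equal-length, non-empty 1-d arrays")
        if np.any(np.diff(x) <= 0):
            raise ArgumentError("knot_exposure must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise DomainError("knot_rr contains non-finite values")
        if np.any(r <= 0):
            raise DomainError("knot_rr must be positive everywhere")

    def normalised_rr(self, exposure: np.ndarray) -> np.ndarray:
        """RR at `exposure`, divided by RR at the TMREL, floored at 1 below
        the TMREL."""
        exposure = np.asarray(exposure, dtype=float)
        rr = np.interp(exposure, self.knot_exposure, self.knot_rr)
        rr_tmrel = float(np.interp(self.tmrel, self.knot_exposure, self.knot_rr))
        out = rr / rr_tmrel
        return np.where(exposure < self.tmrel, 1.0, out)


@dataclass(frozen=True)
class StandardPopulation:
    """Fixed age structure for direct standardisation: ``weight[band]`` is the
    standard population's share in each age band (weights sum to 1)."""

    weights: Mapping[str, float]

    def __post_init__(self):
        w = dict(self.weights)
        object.__setattr__(self, "weights", w)
        vals = np.array(list(w.values()), dtype=float)
        if vals.size == 0 or np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
            raise ArgumentError("standard-population weights must be non-negative and sum to 1 within 1e-9")


@dataclass(frozen=True)
class BurdenResult:
    """Attributable burden for one (measure, population) combination."""

    measure: str  # deaths | yll | daly
    paf: float
    attributable_count: float
    rate_per_100k: float
    uncertainty_interval: tuple | None = field(default=None)  # UI machinery out of scope


def compute_paf(
    dist: ExposureDistribution,
    rr: RelativeRiskCurve,
    tmrels: Sequence[float] | None = None,
) -> float:
    """Population attributable fraction of a binned exposure distribution.

    PAF = (mean RR - 1) / mean RR with mean RR = sum_i p_i RR_i and RR
    normalised at the TMREL. When ``tmrels`` is given, the PAF is the mean of
    the PAFs recomputed at each TMREL value (a cheap stand-in for a TMREL
    distribution).

    With RR >= 1 everywhere the result lies in [0, 1); protective curves
    (RR < 1 somewhere) can yield a negative PAF.
    """
    if tmrels is not None:
        if len(tmrels) == 0:
            raise ArgumentError("tmrels must be non-empty when provided")
        curves = [RelativeRiskCurve(rr.knot_exposure, rr.knot_rr, t) for t in tmrels]
        return float(np.mean([compute_paf(dist, c) for c in curves]))
    mean_rr = float(np.sum(dist.proportion * rr.normalised_rr(dist.bin_mid)))
    if not np.isfinite(mean_rr) or mean_rr <= 0:
        raise DomainError("mean relative risk is non-finite or non-positive")
    return (mean_rr - 1.0) / mean_rr


def attributable_burden(paf: float, total_outcome: float) -> float:
    """Outcome count attributable to the exposure: ``paf * total_outcome``,
    unrounded. A negative PAF (protective exposure) yields a negative count."""
    if total_outcome < 0:
        raise ArgumentError("total_outcome must be non-negative")
    return paf * total_outcome


def rate_per_100k(count: float, population: float) -> float:
    """Express a count as a rate per 100,000 population."""
    if population <= 0:
        raise ArgumentError("population must be positive")
    return 100000.0 * count / population


def age_standardise(age_rates: Mapping[str, float], std: StandardPopulation) -> float:
    """Directly standardised rate: sum of age-band rates weighted by the
    standard population's age shares. Band labels must match exactly."""
    if set(age_rates) != set(std.weights):
        missing = set(std.weights) ^ set(age_rates)
        raise ArgumentError(f"age bands of rates and standard population differ: {sorted(missing)}")
    return float(sum(std.weights[b] * age_rates[b] for b in std.weights))


def percent_change(v_ref: float, v_new: float) -> float:
    """Percent decrease from ``v_ref`` to ``v_new``: 100 (v_ref - v_new)/v_ref.

    Sign convention: POSITIVE means a decrease. Burden reports phrase change
    as "x% lower than the reference year", so a fall from 20.8 to 13.8 reads
    +33.7, and an increase comes out negative.
    """
    if v_ref == 0:
        raise DomainError("reference value must be non-zero")
    return 100.0 * (v_ref - v_new) / v_ref


def share_of_total(part: float, total: float) -> float:
    """Percent share of ``part`` in ``total``."""
    if total <= 0:
        raise ArgumentError("total must be positive")
    if part < 0:
        raise ArgumentError("part must be non-negative")
    return 100.0 * part / total
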