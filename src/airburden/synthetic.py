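"""Synthetic GBD-like country-year panels with known ground truth.

The generator emulates the statistical structure of a European air-pollution
burden panel — 43 countries observed 1990-2019 — without any external data:

* ambient PM2.5 starts in 1990 spread log-uniformly across countries
  (default span 8-45 ug/m3: the observed 2019 country range back-projected
  through the continental decline, with a log-uniform mean near the
  reported 1990 average of ~21 ug/m3) and declines multiplicatively at ~1.4 %/year on
  average (so the 29-year decline is near the observed one third), with
  lognormal country-level jitter so values stay positive;
* household air pollution (HAP) is a positive, time-constant exposure index
  drawn log-uniformly per country;
* the all-cause, all-pollutant YLL rate obeys a known structural log-log law

      YLL rate = exp(b0 + b1 ln(aPM2.5) + b2 ln(HAP) + eps),
      eps ~ Normal(0, noise_sd^2) i.i.d. per country-year,

  with defaults (b0, b1, b2) = (2.476, 1.623, 0.15) and noise_sd = 0.3, so
  the association module has exact ground truth to recover;
* DALY and death rates are fixed multiples of the YLL rate; cause (IHD,
  stroke, TBL cancer) and pollutant (aPM2.5, HAP, ozone) cells are fixed
  configurable shares of the all-cause/all-pollutant cell, so share
  computations have known truth;
* SDI anti-correlates with starting exposure and GNI increases with SDI
  (with noise), so bracket comparisons have a known direction; the
  `n_missing_gni` smallest-population countries get a missing GNI,
  emulating microstates absent from income tables.

Randomness: one root seed; each country draws from its own substream
``default_rng([seed, country_index])`` so adding a country never perturbs
the others, and regeneration with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .burden import ExposureDistribution
from .errors import ArgumentError, ConfigError

__all__ = [
    "SyntheticConfig",
    "generate_panel",
    "generate_exposure_distribution",
    "CAUSES",
    "POLLUTANTS",
]

#: cause tags carried in every panel; shares are of the all-cause cell.
CAUSES = ("all_cause", "ihd", "stroke", "tbl")
#: pollutant tags; shares are of the "all" (total air pollution) cell.
POLLUTANTS = ("all", "apm25", "hap", "ozone")


def _tuple2(v):
    t = tuple(float(x) for x in v)
    if len(t) != 2:
        raise ConfigError(f"expected a (min, max) pair, got {v!r}")
    return t


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic world.

    Defaults are the stated conditions of the emulated panel: 43 countries,
    years 1990-2019, structural coefficients (2.476, 1.623, 0.15) and
    outcome noise 0.3 on the natural-log scale.
    """

    n_countries: int = 43
    years: tuple[int, int] = (1990, 2019)
    seed: int = 0
    b0: float = 2.476
    b1: float = 1.623
    b2: float = 0.15
    noise_sd: float = 0.3
    exposure_start_range: tuple[float, float] = (8.0, 45.0)
    annual_decline_pct: float = 1.4
    hap_range: tuple[float, float] = (1.0, 100.0)
    pop_range: tuple[float, float] = (5e4, 8e7)
    sdi_range: tuple[float, float] = (0.60, 0.97)
    gni_range: tuple[float, float] = (3e3, 1.2e5)
    ozone_range: tuple[float, float] = (38.0, 52.0)
    ozone_annual_decline_pct: float = 0.23
    n_missing_gni: int = 4
    daly_per_yll: float = 1.08
    yll_per_death: float = 20.0
    cause_shares: Mapping[str, float] = field(
        default_factory=lambda: {"ihd": 0.446, "stroke": 0.252, "tbl": 0.107}
    )
    pollutant_shares: Mapping[str, float] = field(
        default_factory=lambda: {"apm25": 0.904, "hap": 0.049, "ozone": 0.047}
    )

    def __post_init__(self):
        for name in (
            "exposure_start_range",
            "hap_range",
            "pop_range",
            "sdi_range",
            "gni_range",
            "ozone_range",
        ):
            object.__setattr__(self, name, _tuple2(getattr(self, name)))
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "cause_shares", dict(self.cause_shares))
        object.__setattr__(self, "pollutant_shares", dict(self.pollutant_shares))
        self._validate()

    def _validate(self):
        if not isinstance(self.seed, int):
            raise ConfigError("seed: must be an integer")
        if self.n_countries < 3:
            raise ConfigError("n_countries: must be >= 3 (medians and group tests need >= 3 units)")
        if len(self.years) != 2 or self.years[0] >= self.years[1]:
            raise ConfigError("years: must be an inclusive (start, end) range spanning >= 2 years")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd: must be >= 0")
        for name in ("exposure_start_range", "hap_range", "pop_range", "sdi_range", "gni_range", "ozone_range"):
            lo, hi = getattr(self, name)
            if lo <= 0:
                raise ConfigError(f"{name}: minimum must be > 0 (log transforms require positive values)")
            if lo >= hi:
                raise ConfigError(f"{name}: minimum must be below maximum")
        if not 0 <= self.annual_decline_pct < 100:
            raise ConfigError("annual_decline_pct: must be in [0, 100)")
        if not 0 <= self.n_missing_gni <= self.n_countries:
            raise ConfigError("n_missing_gni: must be between 0 and n_countries")
        if self.daly_per_yll < 1.0:
            raise ConfigError("daly_per_yll: must be >= 1 (DALY = YLL + YLD)")
        if self.yll_per_death <= 0:
            raise ConfigError("yll_per_death: must be positive")
        for name, shares, keys in (
            ("cause_shares", self.cause_shares, set(CAUSES) - {"all_cause"}),
            ("pollutant_shares", self.pollutant_shares, set(POLLUTANTS) - {"all"}),
        ):
            if set(shares) != keys:
                raise ConfigError(f"{name}: keys must be exactly {sorted(keys)}")
            if any(not 0 < v <= 1 for v in shares.values()) or sum(shares.values()) > 1 + 1e-12:
                raise ConfigError(f"{name}: shares must lie in (0, 1] and sum to at most 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load from JSON or YAML (JSON is a YAML subset; yaml reads both)."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)


def _country_rng(seed: int, index: int) -> np.random.Generator:
    # per-country substream; adding a country never perturbs earlier ones
    return np.random.default_rng([seed % (2**31), index])


def generate_panel(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a tidy country-year panel.

    One row per (country, year, cause, pollutant) with columns: country,
    year, apm25, ozone, hap, population, sdi, gni, cause, pollutant,
    deaths_total, yll_total, daly_total, death_rate, yll_rate, daly_rate.
    Rates are per 100,000 and treated as age-standardised; totals are
    rate x population / 100,000.
    """
    cfg = config
    y0, y1 = cfg.years
    years = np.arange(y0, y1 + 1)
    n_years = years.size

    e_lo, e_hi = cfg.exposure_start_range
    s_lo, s_hi = cfg.sdi_range
    g_lo, g_hi = cfg.gni_range

    frames = []
    populations = np.empty(cfg.n_countries)
    for i in range(cfg.n_countries):
        rng = _country_rng(cfg.seed, i)
        sdi = rng.uniform(s_lo, s_hi)
        u = (sdi - s_lo) / (s_hi - s_lo)
        # starting exposure log-uniform across the range, anti-coupled to SDI
        u_e = float(np.clip(u + rng.normal(0.0, 0.08), 0.0, 1.0))
        apm25_start = np.exp(np.log(e_hi) - u_e * (np.log(e_hi) - np.log(e_lo)))
        decline = np.clip(
            cfg.annual_decline_pct / 100.0 * rng.lognormal(0.0, 0.25), 0.0, 0.5
        )
        hap = np.exp(rng.uniform(np.log(cfg.hap_range[0]), np.log(cfg.hap_range[1])))
        population = np.exp(rng.uniform(np.log(cfg.pop_range[0]), np.log(cfg.pop_range[1])))
        ozone_start = rng.uniform(*cfg.ozone_range)
        o3_decline = np.clip(
            cfg.ozone_annual_decline_pct / 100.0 * rng.lognormal(0.0, 0.25), 0.0, 0.5
        )
        u_g = float(np.clip(u + rng.normal(0.0, 0.12), 0.0, 1.0))
        gni = np.exp(np.log(g_lo) + u_g * (np.log(g_hi) - np.log(g_lo)))
        eps = rng.normal(0.0, cfg.noise_sd, n_years) if cfg.noise_sd > 0 else np.zeros(n_years)

        apm25 = apm25_start * (1.0 - decline) ** (years - y0)
        ozone = ozone_start * (1.0 - o3_decline) ** (years - y0)
        yll_rate = np.exp(cfg.b0 + cfg.b1 * np.log(apm25) + cfg.b2 * np.log(hap) + eps)
        daly_rate = cfg.daly_per_yll * yll_rate
        death_rate = yll_rate / cfg.yll_per_death

        populations[i] = population
        frames.append(
            pd.DataFrame(
                {
                    "country": f"country_{i + 1:02d}",
                    "year": years,
                    "apm25": apm25,
                    "ozone": ozone,
                    "hap": hap,
                    "population": population,
                    "sdi": sdi,
                    "gni": gni,
                    "death_rate": death_rate,
                    "yll_rate": yll_rate,
                    "daly_rate": daly_rate,
                }
            )
        )
    core = pd.concat(frames, ignore_index=True)

    if cfg.n_missing_gni:
        order = np.argsort(populations, kind="stable")
        missing = {f"country_{i + 1:02d}" for i in order[: cfg.n_missing_gni]}
        core.loc[core["country"].isin(missing), "gni"] = np.nan

    # expand to cause x pollutant cells with fixed shares
    cause_share = {"all_cause": 1.0, **cfg.cause_shares}
    poll_share = {"all": 1.0, **cfg.pollutant_shares}
    cells = []
    for cause in CAUSES:
        for poll in POLLUTANTS:
            cell = core.copy()
            frac = cause_share[cause] * poll_share[poll]
            cell["cause"] = cause
            cell["pollutant"] = poll
            for col in ("death_rate", "yll_rate", "daly_rate"):
                cell[col] = core[col] * frac
            cells.append(cell)
    panel = pd.concat(cells, ignore_index=True)
    for rate, total in (
        ("death_rate", "deaths_total"),
        ("yll_rate", "yll_total"),
        ("daly_rate", "daly_total"),
    ):
        panel[total] = panel[rate] * panel["population"] / 100000.0
    cols = [
        "country", "year", "cause", "pollutant",
        "apm25", "ozone", "hap", "population", "sdi", "gni",
        "deaths_total", "yll_total", "daly_total",
        "death_rate", "yll_rate", "daly_rate",
    ]
    return panel[cols].sort_values(["country", "year", "cause", "pollutant"]).reset_index(drop=True)


def generate_exposure_distribution(
    mean: float, sd: float, n_bins: int, lower: float, upper: float
) -> ExposureDistribution:
    """Binned truncated-normal exposure distribution on [lower, upper].

    Bin proportions are the normal mass falling in each of ``n_bins`` equal
    bins, renormalised to the truncated support, and assigned to bin
    midpoints.
    """
    if mean <= 0 or sd <= 0:
        raise ArgumentError("mean and sd must be positive")
    if not lower < upper:
        raise ArgumentError("lower must be below upper")
    if n_bins < 1:
        raise ArgumentError("n_bins must be >= 1")
    edges = np.linspace(lower, upper, n_bins + 1)
    cdf = stats.norm.cdf(edges, loc=mean, scale=sd)
    mass = np.diff(cdf)
    total = mass.sum()
    if total <= 1e-300:
        raise ArgumentError("support [lower, upper] carries no probability mass")
    return ExposureDistribution(bin_mid=(edges[:-1] + edges[1:]) / 2.0, proportion=mass / total)
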