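# airburden

Attributable burden of air pollution on country-year panels: population
attributable fractions, median-relative ratio statistics, log-log
exposure–outcome regression with elasticity interpretation, and
development-bracket comparisons.

## Who this is for

Epidemiologists and environmental-health analysts comparing countries (or
any regions) on burden attributable to an exposure — here ambient PM2.5
(aPM2.5), household air pollution (HAP) and ozone, with deaths, years of
life lost (YLL) and disability-adjusted life years (DALYs) as outcomes.
Everything runs on tidy CSV panels; a synthetic generator with known ground
truth makes the whole pipeline testable without access to burden-study
databases.

## The statistics at its core

**Attributable burden.** With a binned exposure distribution `p_i` at
exposures `x_i` and a relative-risk curve normalised to `RR(TMREL) = 1`,

    PAF = (Σ p_i RR(x_i) − 1) / (Σ p_i RR(x_i)),
    attributable burden = PAF × total outcome,

expressed as counts, rates per 100,000, and directly age-standardised rates.

**Median-relative ratios.** A country's metric divided by the all-country
median of the same year; the change of that ratio between two anchor years,

    change = (ratio_start − ratio_end) / ratio_start,

is positive exactly when the country out-reduced the median country.
Instances: DARR (DALY rate), PMR (aPM2.5), YRR (YLL rate), DRR (death
rate), each classified positive / neutral / negative per country.

**Elasticity regression.** OLS of `ln(YLL rate)` on `ln(aPM2.5)` and
`ln(HAP)`; a slope `b` means a 10% predictor increase changes the outcome
by `100(1.1^b − 1)`%.

**Group comparisons.** Countries bracketed by socio-demographic index
(low/medium/high) or GNI per capita (merged middle → very high income);
bracket medians with Tukey IQRs, Kruskal–Wallis by ranks and Dunn's
pairwise tests with Bonferroni correction, all tie-corrected on mid-ranks.

## Worked example

```python
from airburden import SyntheticConfig, generate_panel, fit_loglog, elasticity, classify_panel

panel = generate_panel(SyntheticConfig(seed=1))   # 43 countries, 1990-2019
e = panel[(panel.cause == "all_cause") & (panel.pollutant == "all") & (panel.year == 2019)]

fit = fit_loglog(e["yll_rate"].to_numpy(),
                 {"apm25": e["apm25"].to_numpy(), "hap": e["hap"].to_numpy()})
print(fit.model_string())
print(f"R^2 = {fit.r_squared:.3f}; +10% aPM2.5 -> YLL {elasticity(fit.coef['apm25'], 0.10):+.1f}%")

darr = classify_panel(panel, metric="daly_rate")
print(darr["classification"].value_counts().to_dict())
```

prints

```
log(YLL) = 2.436 + 1.624 × log(apm25) + 0.136 × log(hap)
R^2 = 0.887; +10% aPM2.5 -> YLL +16.7%
{'negative': 26, 'positive': 17}
```

The panel was generated from the structural law
`YLL = exp(2.476 + 1.623 ln aPM2.5 + 0.15 ln HAP + ε)`, so the fit recovers
the slopes within sampling error; the elasticity says a 10% rise in ambient
PM2.5 carries a ~17% rise in years of life lost, an order of magnitude more
than household air pollution. The DARR classification counts say how many
countries reduced their DALY rate at least as fast as the median country.

The `examples/` directory has one narrative script per capability
(synthetic panels, PAF → burden, ratio statistics, regression, group
comparisons, the full report); each prints its numbers with a line on what
they mean. `docs/methods.md` documents the model, parameter defaults, and
what the synthetic world does and does not emulate.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic panel from the given seed and runs the
complete pipeline end to end — burden shares and percent changes, all four
ratio statistics, the log-log fit with elasticities, and the SDI/GNI group
tests — writing its JSON results object to `--out` (report files land under
`scratch/`).
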