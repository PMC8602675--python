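# Methods

## Scope and model

`airburden` implements the analysis chain used in cross-country
environmental burden-of-disease studies: attributable burden via population
attributable fractions, median-relative "league table" ratio statistics, a
log-log exposure–outcome regression read as elasticities, and nonparametric
comparisons of development brackets. All stages run on tidy country-year
panels; a synthetic generator provides panels with known ground truth so
every stage is testable without external downloads.

### Attributable burden

For a continuous exposure summarised as a binned distribution
(proportion `p_i` of the population at exposure `x_i`) and a relative-risk
curve `RR(x)` normalised so `RR(TMREL) = 1`,

    PAF = (Σ_i p_i RR(x_i) − 1) / (Σ_i p_i RR(x_i)).

Numerical choices: the RR curve is linearly interpolated between knots,
extrapolated flat beyond the end knots, and floored at 1 below the TMREL
(exposure under the theoretical minimum carries no excess risk). The TMREL
is a point value; a list of TMRELs may be supplied, in which case the PAF is
the mean over them — a closed-form-friendly stand-in for a TMREL
distribution. With `RR ≥ 1` everywhere, `PAF ∈ [0, 1)`; protective curves
yield negative PAFs, which propagate as negative attributable counts rather
than being clipped.

Attributable burden is `PAF × total outcome` (deaths, YLL or DALYs),
unrounded; rates are per 100,000; direct age standardisation is the
weighted sum of age-band rates under a fixed standard population. No
uncertainty intervals are computed — draw-level UI machinery belongs to the
upstream burden studies, and results carry an empty UI field.

`percent_change(ref, new) = 100 (ref − new)/ref` is **positive for a
decrease**, matching the convention of burden reports that phrase change as
"x% lower than the reference year". Printed-precision comparisons round
half-away-from-zero (`round_half_away`), the convention of published
tables; computation stays at full precision throughout.

### Median-relative ratio statistics

For metric `m` and year `t`, a country's ratio is
`m_country(t) / median_countries(m(t))`; the country is included in its own
reference median (a literal reading of "all countries", and the only choice
that makes the median identical for every country). The change between
anchor years is `(r_start − r_end)/r_start`, positive exactly when the
country's own relative reduction exceeds the median country's (an algebraic
identity that is property-tested). Classification: |change| ≤ 5e-3 →
neutral (half a unit at one-decimal percent printing, configurable),
otherwise by sign. The four shipped instances — DARR (DALY rate), PMR
(aPM2.5), YRR (YLL rate), DRR (death rate) — differ only in the metric
column they read; DARR defaults to the age-standardised all-cause DALY rate
attributable to air pollution.

### Regression and elasticities

`fit_loglog` is OLS on natural logs of outcome and predictors (the "log" in
the displayed model is read as ln), solved by `numpy.linalg.lstsq` (SVD)
with classical variance algebra: `Var(b) = σ² (XᵀX)⁻¹`,
`σ² = RSS/(n − k − 1)`, t-based coefficient p-values and the overall F
test. Non-positive values raise instead of being offset — an additive
offset silently changes the elasticity interpretation, so filtering is the
caller's explicit decision. A slope `b` means a `(1+p)`-fold predictor
increase multiplies the outcome by `(1+p)^b`; `elasticity(b, p)` returns
`100((1+p)^b − 1)`, so the default structural slope 1.623 gives +16.7% YLL
per +10% aPM2.5 and 0.15 gives +1.4% per +10% HAP. On noiseless data the
F statistic is reported as infinity with p = 0.

### Rank tests

Mid-ranks are used everywhere. Spearman is the Pearson correlation of
mid-ranks with the t approximation on n − 2 df. Kruskal–Wallis uses the
tie-corrected H (division by `1 − Σ(t³ − t)/(N³ − N)`; H defined as 0 when
all observations tie) and a chi-square tail with k − 1 df. Dunn's pairwise
z uses the tie-corrected variance `N(N+1)/12 − Σ(t³ − t)/(12(N−1))`, a
two-sided normal tail, and Bonferroni adjustment by the number of
comparisons actually performed, k(k−1)/2. For total n ≤ 10,
`kruskal_wallis_exact` and `dunn_exact` enumerate all
`n!/(n_1!…n_k!)` labelled assignments and return exact permutation
p-values; they exist as oracles, and at such n the chi-square/normal
approximations deviate from them by up to ~0.15 absolute in p — the test
suite asserts statistic identity exactly and bounds the approximation error
rather than pretending the approximations are exact at n = 9.

### Development brackets

SDI: low [0, 0.750), medium [0.750, 0.850), high [0.850, 1]. The printed
bracket definitions ("< 0.749", "> 0.850") leave the slivers (0.749, 0.750)
and (0.849, 0.850) unassigned; half-open intervals close them because a
partition must cover all values. GNI (Atlas US$): merged middle
[1,036, 12,536), lower high [12,536, 36,767), moderate high
[36,767, 60,998), very high ≥ 60,998 — the two World Bank middle bands are
merged and the high band split three ways, mirroring the analysis design for
a mostly-high-income region. Quartiles default to Tukey median-of-halves
with the median excluded for odd n (so {1..5} → (1.5, 4.5)); the rule is a
parameter because published tables rarely state theirs. Countries with
missing GNI are excluded from GNI analyses and returned as an explicit
exclusion list, never dropped silently; empty brackets are reported with
n = 0 and NaN summaries.

## The synthetic world

Defaults state the emulated panel: 43 countries, years 1990–2019, and the
structural law

    YLL rate = exp(2.476 + 1.623 ln aPM2.5 + 0.15 ln HAP + ε),
    ε ~ N(0, 0.3²) i.i.d. per country-year.

Parameter choices and their grounds:

| parameter | default | why |
|---|---|---|
| `exposure_start_range` | (8, 45) μg/m³ | observed 2019 country range back-projected through the continental decline; log-uniform mean ≈ 21, near the reported 1990 average |
| `annual_decline_pct` | 1.4 %/yr | (1 − 0.014)²⁹ ≈ 0.66, the reported ~34% 29-year decline |
| `noise_sd` | 0.3 | residual spread on the ln scale that reproduces the reported R² ≈ 0.89 order of fit at n = 43 |
| `hap_range` | (1, 100), log-uniform | HAP has no published unit; only positivity and spread matter to the regression |
| `pop_range` | (5·10⁴, 8·10⁷), log-uniform | microstates to large states |
| `sdi_range` | (0.60, 0.97) | spans all three SDI brackets |
| `gni_range` | (3·10³, 1.2·10⁵) US$ | spans merged-middle through very-high income |
| `cause_shares` | IHD 0.446, stroke 0.252, TBL 0.107 | the reported cause composition of attributable deaths |
| `pollutant_shares` | aPM2.5 0.904, HAP 0.049, ozone 0.047 | reported pollutant composition, trimmed to sum to 1 |
| `daly_per_yll`, `yll_per_death` | 1.08, 20 | DALY slightly above YLL (YLD is small for these causes); ~20 life-years lost per attributable death |
| `n_missing_gni` | 4 | four microstates lack GNI; the 4 smallest-population countries are marked missing |

Couplings: starting exposure is log-uniform but anti-coupled to SDI
(jittered), and GNI increases with SDI (jittered), so bracket comparisons
have a known direction and SDI–GNI rank correlation is strongly positive.
Ozone declines slowly (~0.23 %/yr, the reported ~6.5% over 29 years) and is
deliberately unrelated to the outcome, mirroring its exclusion from the
regression.

Randomness contract: one root seed; country *i* draws from
`default_rng([seed, i])`, so regeneration is bit-identical and adding a
country never perturbs the others.

**What the generator does not emulate**, hence what a green test does not
establish: no gridded or age-structured exposure (rates are generated
directly as "age-standardised"); HAP and population are constant over time;
cause and pollutant cells are *fixed shares* of the all-cause cell, so
cross-country ranks are identical across causes — cause-specific
Kruskal–Wallis H values coincide on synthetic panels where real data would
differ; no serial correlation in ε; no uncertainty intervals. Real-data
quantities that depend on the actual panel (the published r = 0.911,
R² = 0.885, the 26-of-43 / 31-of-43 classification counts, the 11-fold
bracket ratios) are therefore covered only directionally, never asserted
numerically.

## Known limitations

- The PAF form is the discrete-bin continuous-risk formula; upstream
  burden studies use draw-level machinery and TMREL distributions that are
  out of scope here.
- The neutral band on ratio changes encodes printed-precision semantics; at
  tolerance 0 nearly every country would be signed.
- Exact permutation tests are capped at n = 10 (multinomial enumeration
  grows fast); beyond that the asymptotic approximations are the only
  route, as in standard practice.
- `read_panel` validates record invariants and aggregation consistency but
  does not check cross-year continuity (a country may appear in some years
  only); the ratio stage enforces anchor-year completeness itself.
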