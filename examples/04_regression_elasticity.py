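"""Log-log regression of the YLL rate on aPM2.5 and HAP, read as
elasticities.

The model ln(YLL) = b0 + b1 ln(aPM2.5) + b2 ln(HAP) makes the slopes
elasticity-type coefficients: a 10% rise in a predictor changes the
outcome by 100 (1.1^b - 1) percent.
"""

from airburden import SyntheticConfig, elasticity, fit_loglog, generate_panel, spearman

panel = generate_panel(SyntheticConfig(seed=1))
e = panel[(panel.cause == "all_cause") & (panel.pollutant == "all") & (panel.year == 2019)]

fit = fit_loglog(
    e["yll_rate"].to_numpy(),
    {"apm25": e["apm25"].to_numpy(), "hap": e["hap"].to_numpy()},
)
print(fit.model_string())
print(f"R^2 = {fit.r_squared:.3f}, F({fit.df_model},{fit.df_resid}) = {fit.f_stat:.1f}, "
      f"p = {fit.f_pvalue:.2e}, n = {fit.n}")
for name, b in fit.coef.items():
    print(f"  {name}: b = {b:.3f} (SE {fit.se[name]:.3f}), "
          f"+10% -> YLL {elasticity(b, 0.10):+.1f}%")

rho = spearman(e["apm25"].to_numpy(), e["yll_rate"].to_numpy())
print(f"Spearman r (YLL rate vs aPM2.5) = {rho.statistic:.3f}, p = {rho.p_value:.2e}")
print("\nThe generator's structural slopes are (1.623, 0.15); the fit recovers")
print("them within sampling error, and the elasticities say ambient PM2.5")
print("dominates household air pollution as a driver of years of life lost.")
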