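"""Do higher-development countries carry less attributable burden?

Countries are bracketed by socio-demographic index (SDI: low / medium /
high) and by GNI per capita (merged middle, lower high, moderate high, very
high income); bracket medians are compared with Kruskal-Wallis and Dunn's
pairwise tests (Bonferroni-corrected).
"""

from airburden import (
    SyntheticConfig,
    compare_groups,
    fold_ratio,
    generate_panel,
    gni_scheme,
    group_summary,
    sdi_scheme,
)

panel = generate_panel(SyntheticConfig(seed=1))

summary, _ = group_summary(panel, sdi_scheme(), measure="daly_rate", cause="ihd", year=2019)
print("IHD DALY rate attributable to air pollution, 2019, by SDI bracket:")
print(summary.to_string(index=False))
s = summary.set_index("bracket")
print(f"low/high fold ratio = {fold_ratio(s.loc['low', 'median'], s.loc['high', 'median']):.1f}x\n")

tests = compare_groups(panel, sdi_scheme(), measure="daly_rate", causes=("ihd", "stroke", "tbl"))
kw = tests[tests.test == "kruskal-wallis"]
for _, r in kw.iterrows():
    print(f"Kruskal-Wallis {r.cause}: H({int(r.df)}) = {r.statistic:.3f}, p = {r.p_value:.2e}")

print("\nDunn pairwise (IHD, Bonferroni-adjusted p):")
for _, r in tests[(tests.test == "dunn") & (tests.cause == "ihd")].iterrows():
    print(f"  {r.pair}: z = {r.statistic:+.2f}, adj p = {r.adjusted_p:.4f}")

gni_summary, excluded = group_summary(panel, gni_scheme(), measure="daly_rate", cause="ihd")
print(f"\nGNI analysis runs on {int(gni_summary.n.sum())} countries; "
      f"excluded for missing GNI: {', '.join(excluded)}")
print("Lower brackets carry systematically higher attributable burden because")
print("the generator couples exposure inversely to development, as observed.")
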