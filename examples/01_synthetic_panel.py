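"""Generate a GBD-like country-year panel and inspect its structure.

The panel emulates 43 European countries observed 1990-2019: declining
ambient PM2.5, a constant household-air-pollution index, and burden rates
(deaths, YLL, DALYs per 100,000) generated from a known log-log law, split
into cause and pollutant cells with fixed shares.
"""

from airburden import SyntheticConfig, generate_panel

panel = generate_panel(SyntheticConfig(seed=1))
print(f"{panel.shape[0]} rows = 43 countries x 30 years x 4 causes x 4 pollutants\n")

one = panel[(panel.country == "country_01") & (panel.year == 2019)]
print("country_01 in 2019 (all-cause row per pollutant):")
print(
    one[one.cause == "all_cause"][
        ["pollutant", "apm25", "hap", "deaths_total", "yll_rate", "daly_rate"]
    ].to_string(index=False)
)

start = panel[(panel.year == 1990)]["apm25"].mean()
end = panel[(panel.year == 2019)]["apm25"].mean()
print(f"\nMean aPM2.5: {start:.1f} ug/m3 in 1990 -> {end:.1f} ug/m3 in 2019")
print("Each country's exposure declines multiplicatively (~1.4%/yr on average),")
print("so the 29-year drop lands near one third, as in the European record.")
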