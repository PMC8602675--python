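"""From an exposure distribution and a relative-risk curve to attributable
deaths.

PAF = (sum_i p_i RR_i - 1) / (sum_i p_i RR_i), with the RR curve normalised
to 1 at the theoretical minimum risk exposure level (TMREL). Multiplying
the PAF by the total outcome gives the attributable count, expressible as a
rate per 100,000.
"""

from airburden import (
    RelativeRiskCurve,
    attributable_burden,
    compute_paf,
    generate_exposure_distribution,
    rate_per_100k,
)

# population exposure: truncated normal around 20.8 ug/m3 (a 1990-like
# European mean), binned for the discrete PAF sum
dist = generate_exposure_distribution(mean=20.8, sd=6.0, n_bins=50, lower=0.0, upper=60.0)

# a stylised monotone RR curve with TMREL at 5 ug/m3
rr = RelativeRiskCurve(
    knot_exposure=[0.0, 5.0, 20.0, 40.0, 60.0],
    knot_rr=[1.0, 1.0, 1.25, 1.45, 1.55],
    tmrel=5.0,
)

paf = compute_paf(dist, rr)
total_deaths = 368_006.0  # all deaths in the population this year
attributable = attributable_burden(paf, total_deaths)
rate = rate_per_100k(attributable, population=742_000_000)

print(f"PAF = {paf:.4f}  (fraction of deaths attributable to exposure above TMREL)")
print(f"Attributable deaths = {attributable:,.0f} of {total_deaths:,.0f}")
print(f"Attributable death rate = {rate:.2f} per 100,000")
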