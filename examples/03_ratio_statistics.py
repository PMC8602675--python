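"""Median-relative ratio statistics: who keeps pace with the regional median?

A country's DALY rate (or PM2.5 level) is divided by the all-country median
of the same year; the relative decline of that ratio between 1990 and 2019
is positive exactly when the country out-reduced the median. DARR uses the
DALY rate, PMR the PM2.5 concentration, YRR the YLL rate, DRR the death
rate.
"""

from airburden import SyntheticConfig, classify_panel, generate_panel

panel = generate_panel(SyntheticConfig(seed=1))

for name, metric in [("DARR", "daly_rate"), ("PMR", "apm25")]:
    out = classify_panel(panel, metric=metric, year_start=1990, year_end=2019)
    counts = out["classification"].value_counts()
    print(f"{name} change ({metric}):")
    print(
        f"  {counts.get('positive', 0)} positive (out-reduced the median), "
        f"{counts.get('neutral', 0)} neutral, "
        f"{counts.get('negative', 0)} negative of {len(out)} countries"
    )
    best = out.nlargest(2, "change")
    worst = out.nsmallest(1, "change")
    for _, r in best.iterrows():
        print(f"  best: {r.country}  change = {100 * r.change:+.1f}%")
    for _, r in worst.iterrows():
        print(f"  worst: {r.country}  change = {100 * r.change:+.1f}%")
    print()

print("A negative change does not mean the country worsened in absolute terms -")
print("only that its own reduction fell short of the median country's pace.")
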