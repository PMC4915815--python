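"""Downstream summaries: calendar dates, date densities, gene-flow edges.

Takes characterised admixture events and turns them into the quantities a
study reports: calendar dates, per-region date densities weighted by
source composition, and country-level gene-flow arrows.
"""

import numpy as np

import haplomix as hm
from haplomix.globetrotter import AdmixtureEvent

# a characterised event: alpha = 6% with a minor source spread over four
# surrogate groups (compare the per-group weights against 100 * alpha *
# coefficient by hand)
event = AdmixtureEvent(
    classification="one date",
    dates=[24.0],
    date_ci=[(17.0, 31.0)],
    alpha=0.06,
    sources=[{
        "alpha": 0.06,
        "source1": np.array([0.02, 0.15, 0.26, 0.57]),
        "source2": np.array([0.90, 0.05, 0.03, 0.02]),
    }],
    metrics={"max_r1": 0.9, "fq1": 0.95, "fq2": 0.97, "m": 0.1},
    p_value=0.0,
    bootstrap_dates=list(np.random.default_rng(0).normal(24, 3, 100)),
    surrogates=["massai", "afar", "gbr", "gih"],
)

year = hm.generations_to_year(event.dates[0])
print(f"date: {event.dates[0]:.0f} generations = {hm.format_year(year)}")

density = hm.build_date_density(
    {"kauma": event},
    {"massai": "East Africa", "afar": "Afroasiatic", "gbr": "Eurasia",
     "gih": "Eurasia"},
)
minor = density.table[density.table.side == "minor"]
print("minor-source date-density weights (percent of total ancestry):")
for _, row in minor.iterrows():
    print(f"  {row.region}: {row.weight:.2f}")
print(f"minor-side total = {density.side_total('kauma', 'minor'):.1f}"
      f" = 100 x alpha = {100 * event.alpha:.1f} (mass conserved exactly)")

edges = hm.aggregate_geneflow_edges(
    {"kauma": event},
    {"massai": "Kenya", "afar": "Ethiopia", "gbr": "UK", "gih": "India"},
    {"kauma": "Malawi"},
)
print("gene-flow edges (origin -> recipient, summed composition weight):")
for e in edges:
    print(f"  {e.origin} -> {e.recipient}: {e.weight:.3f}")

print(f"back-of-envelope spread rate: "
      f"{hm.spread_rate(4000, 2000):.0f} km/year over 4000 km / 2000 years")
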