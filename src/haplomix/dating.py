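"""Calendar conversion, date densities, and gene-flow aggregation.

Admixture dates in generations convert to calendar years via
D = 1950 - (n + 1) * g with generation time g (default 29 years);
positive D is CE, negative BCE.  Weighted-LD confidence intervals quoted
as 1 SE are scaled by 1.96 for comparability with bootstrap 95% CIs.

Date densities spread each event's bootstrap dates over the surrogate
components of its sources, weighted by composition coefficient times the
side's admixture proportion times 100 (percent); the minor side of an
event carries exactly 100*alpha mass and the major side 100*(1-alpha).
Gene-flow edges aggregate source compositions by country of origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .globetrotter import AdmixtureEvent

__all__ = [
    "generations_to_year",
    "year_to_generations",
    "scale_confidence_interval",
    "format_year",
    "spread_rate",
    "DateDensity",
    "build_date_density",
    "FlowEdge",
    "aggregate_geneflow_edges",
]

GENERATION_YEARS = 29.0


def generations_to_year(n, g: float = GENERATION_YEARS):
    """Calendar year D = 1950 - (n + 1) * g for n generations ago."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("generations since admixture must be nonnegative")
    d = 1950 - (n + 1) * g
    return float(d) if d.ndim == 0 else d


def year_to_generations(year, g: float = GENERATION_YEARS):
    """Inverse of :func:`generations_to_year`."""
    year = np.asarray(year, dtype=float)
    n = (1950 - year) / g - 1
    return float(n) if n.ndim == 0 else n


def scale_confidence_interval(se: float, z: float = 1.96) -> float:
    """95% half-width from a 1-SE interval: 1.96 * se."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    return z * se


def format_year(year: float) -> str:
    """Render a calendar year as e.g. '1225CE' or '297BCE'."""
    y = int(round(year))
    return f"{y}CE" if y >= 0 else f"{-y}BCE"


def spread_rate(distance_km: float = 4000.0, years: float = 2000.0) -> float:
    """Back-of-envelope haplotype spread rate in km/year."""
    if years <= 0:
        raise ValueError("years must be positive")
    return distance_km / years


@dataclass
class DateDensity:
    """Weighted bootstrap-date collections per (region, source side).

    ``weights`` rows: event_id, region, side ('minor'/'major'), weight in
    percent; each row's bootstrap dates are those of its event.
    """

    table: pd.DataFrame
    bootstrap_dates: dict  # event_id -> list of dates (generations)

    def side_total(self, event_id, side) -> float:
        t = self.table
        sel = (t.event_id == event_id) & (t.side == side)
        return float(t.weight[sel].sum())


def build_date_density(
    events: dict[str, AdmixtureEvent],
    region_of_surrogate: dict,
) -> DateDensity:
    """Distribute event compositions into per-region date-density weights.

    For each event and each date's two sources, every surrogate's
    composition coefficient is multiplied by 100 and by the side's
    proportion (alpha for the minor source, 1-alpha for the major), then
    summed within ancestry regions.  Every bootstrap date of the event is
    attached at those weights.
    """
    rows = []
    boots = {}
    for event_id, ev in events.items():
        if not len(ev.bootstrap_dates):
            raise ValueError(f"event {event_id!r} has no bootstrap dates")
        boots[event_id] = [d for d in ev.bootstrap_dates if np.isfinite(d)]
        src = ev.sources[0]
        alpha = src["alpha"]
        for side, comp, prop in (
            ("minor", src["source1"], alpha),
            ("major", src["source2"], 1 - alpha),
        ):
            acc: dict[str, float] = {}
            for s, coef in zip(ev.surrogates, comp):
                region = region_of_surrogate.get(s, s)
                acc[region] = acc.get(region, 0.0) + 100.0 * prop * float(coef)
            for region, wgt in acc.items():
                rows.append((event_id, region, side, wgt))
    table = pd.DataFrame(rows, columns=["event_id", "region", "side", "weight"])
    return DateDensity(table=table, bootstrap_dates=boots)


@dataclass
class FlowEdge:
    """Directed, weighted gene-flow edge between countries."""

    origin: str
    recipient: str
    weight: float
    event_ids: list
    date_window: tuple


def aggregate_geneflow_edges(
    events: dict[str, AdmixtureEvent],
    country_of_surrogate: dict,
    recipient_country: dict,
    component_filter=None,
) -> list[FlowEdge]:
    """Aggregate source compositions into origin-country flow edges.

    Composition coefficients of both sources (weighted by their
    proportions) are summed by origin country; arrows point from the
    country of component origin to the recipient's country.
    ``component_filter`` is an optional predicate on surrogate names
    mirroring the map panels (e.g. keep only Eurasian surrogates).
    """
    acc: dict[tuple, dict] = {}
    for event_id, ev in events.items():
        rc = recipient_country[event_id]
        for src in ev.sources:
            for side, prop in (("source1", src["alpha"]), ("source2", 1 - src["alpha"])):
                for s, coef in zip(ev.surrogates, src[side]):
                    if coef <= 0:
                        continue
                    if component_filter is not None and not component_filter(s):
                        continue
                    if s not in country_of_surrogate:
                        raise ValueError(f"surrogate {s!r} has no country")
                    key = (country_of_surrogate[s], rc)
                    e = acc.setdefault(
                        key, {"weight": 0.0, "events": set(), "dates": []}
                    )
                    e["weight"] += float(prop * coef)
                    e["events"].add(event_id)
                    e["dates"].extend(ev.dates)
    return [
        FlowEdge(
            origin=o, recipient=r, weight=v["weight"],
            event_ids=sorted(v["events"]),
            date_window=(min(v["dates"]), max(v["dates"])) if v["dates"] else (np.nan, np.nan),
        )
        for (o, r), v in sorted(acc.items())
    ]
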