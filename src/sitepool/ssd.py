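"""Standardised site differences and the pooling (equivalence) verdict.

For each domain, SSD_i = (adjusted site mean_i - pooled adjusted mean) /
pooled SD — the site's displacement in units of the all-sites SD. Sites with
|SSD| <= 0.5 (a closed band: values printed as outside are those strictly
beyond +/-0.50) are considered compatible with pooling the sites into a
single standard. Comparisons are organised into a primary item set (seven
directly assessed/observed domains plus the two gross-motor milestone ages)
and a secondary set (language and behaviour domains).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .adjust import AdjustedScores, SiteSummary, adjust_scores, dropped_sites, site_summaries
from .errors import ConfigurationError, DegenerateScaleError, DesignError

logger = logging.getLogger(__name__)

__all__ = [
    "SSDResult",
    "PoolabilityReport",
    "DEFAULT_ITEM_SETS",
    "compute_ssd",
    "apply_band",
    "poolability_analysis",
]

#: default primary/secondary item membership (9 + 7 items)
DEFAULT_ITEM_SETS = {
    "primary": (
        "cognitive",
        "executive_function",
        "attentional_problems",
        "visual_acuity",
        "visual_contrast_sensitivity",
        "fine_motor",
        "gross_motor",
        "age_stood",
        "age_walked",
    ),
    "secondary": (
        "receptive_language",
        "expressive_language",
        "positive_behaviour",
        "negative_behaviour",
        "total_behaviour",
        "emotional_reactivity",
        "positive_affect",
    ),
}


@dataclass(frozen=True)
class SSDResult:
    domain: str
    site_id: str
    ssd: float
    n: int
    within_band: bool


@dataclass(frozen=True)
class PoolabilityReport:
    item_sets: dict
    band: float
    comparisons_total: int
    comparisons_per_set: dict  # set name -> count
    outside_per_set: dict  # set name -> count
    outside_band: tuple  # SSDResult outside the band, any set
    dropped_cells: tuple  # (domain, site) pairs with no complete cases
    verdict_per_set: dict  # set name -> bool (no value outside the band)

    def summary(self) -> str:
        lines = [f"Equivalence band: +/-{self.band} pooled SD (closed)"]
        for name in self.item_sets:
            lines.append(
                f"  {name}: {self.outside_per_set[name]} of "
                f"{self.comparisons_per_set[name]} comparisons outside the band"
                + ("" if self.verdict_per_set[name] else " -> review before pooling")
            )
        lines.append(f"  total comparisons: {self.comparisons_total}")
        return "\n".join(lines)


def compute_ssd(
    summaries: list[SiteSummary], pooled: SiteSummary, domain: str, band: float = 0.5
) -> list[SSDResult]:
    """SSD per site for one domain from adjusted summaries."""
    if len(summaries) < 2:
        raise DesignError("SSD needs >= 2 sites")
    if not pooled.adj_sd > 0:
        raise DegenerateScaleError(
            f"domain {domain!r}: pooled SD is {pooled.adj_sd}; SSD undefined"
        )
    out = []
    for s in summaries:
        ssd = (s.adj_mean - pooled.adj_mean) / pooled.adj_sd
        out.append(
            SSDResult(
                domain=domain,
                site_id=s.site_id,
                ssd=float(ssd),
                n=s.n,
                within_band=abs(ssd) <= band,
            )
        )
    return out


def apply_band(
    ssds: list[SSDResult],
    band: float = 0.5,
    item_sets: dict | None = None,
    dropped_cells: list[tuple[str, str]] | None = None,
) -> PoolabilityReport:
    """Flag each SSD against the closed band and count per item set.

    Domains not assigned to any configured set are collected under "other".
    """
    if not band > 0:
        raise ConfigurationError("band: must be > 0")
    item_sets = dict(item_sets if item_sets is not None else DEFAULT_ITEM_SETS)
    membership = {}
    for name, items in item_sets.items():
        for it in items:
            membership[it] = name

    flagged = [
        SSDResult(r.domain, r.site_id, r.ssd, r.n, abs(r.ssd) <= band) for r in ssds
    ]
    present_other = sorted({r.domain for r in flagged if r.domain not in membership})
    if present_other:
        item_sets["other"] = tuple(present_other)
        for it in present_other:
            membership[it] = "other"

    comparisons = {name: 0 for name in item_sets}
    outside_n = {name: 0 for name in item_sets}
    outside = []
    for r in flagged:
        name = membership[r.domain]
        comparisons[name] += 1
        if not r.within_band:
            outside_n[name] += 1
            outside.append(r)
    return PoolabilityReport(
        item_sets={k: tuple(v) for k, v in item_sets.items()},
        band=band,
        comparisons_total=len(flagged),
        comparisons_per_set=comparisons,
        outside_per_set=outside_n,
        outside_band=tuple(outside),
        dropped_cells=tuple(dropped_cells or ()),
        verdict_per_set={k: outside_n[k] == 0 for k in item_sets},
    )


def poolability_analysis(
    cohort: pd.DataFrame,
    domains: list[str] | None = None,
    band: float = 0.5,
    item_sets: dict | None = None,
    age_center: float = 24.0,
) -> tuple[pd.DataFrame, PoolabilityReport]:
    """Full SSD pipeline: adjust every domain, summarise, standardise, flag.

    Returns a tidy DataFrame (domain, site_id, n, ssd, within_band) and the
    PoolabilityReport. A (domain, site) cell with no complete cases is
    dropped and logged, not an error.
    """
    from .cohort import domain_columns

    if domains is None:
        domains = domain_columns(cohort)
    all_ssd: list[SSDResult] = []
    dropped: list[tuple[str, str]] = []
    for d in domains:
        adj = adjust_scores(cohort, d, age_center=age_center)
        for site in dropped_sites(cohort, adj):
            dropped.append((d, site))
        summaries, pooled = site_summaries(adj)
        all_ssd.extend(compute_ssd(summaries, pooled, d, band=band))
    report = apply_band(all_ssd, band=band, item_sets=item_sets, dropped_cells=dropped)
    table = pd.DataFrame(
        [
            {
                "domain": r.domain,
                "site_id": r.site_id,
                "n": r.n,
                "ssd": r.ssd,
                "within_band": abs(r.ssd) <= band,
            }
            for r in all_ssd
        ]
    )
    return table, report
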