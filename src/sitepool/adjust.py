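"""Sex- and age-adjusted scores and site/pooled summaries.

One pooled least-squares model ``outcome ~ 1 + (age - 24) + 1[boy]`` is fit
across all sites (complete cases for the domain). The adjusted value of a
child is its residual plus the model prediction at the reference covariates:
age 24 months and sex at the pooled boy-fraction (marginal standardisation).
A single pooled model is essential: per-site adjustment would absorb the
site differences the downstream comparison is meant to measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CollinearityError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = ["AdjustedScores", "SiteSummary", "adjust_scores", "site_summaries"]


@dataclass(frozen=True)
class AdjustedScores:
    """Adjusted child-level values for one domain.

    ``values`` is indexed like the complete-case rows of the source cohort
    (``child_id`` index); ``reference_age`` / ``reference_boy_fraction`` are
    the covariate values the scores are standardised to.
    """

    domain: str
    values: pd.Series
    site_id: pd.Series
    reference_age: float
    reference_boy_fraction: float
    coefficients: dict

    @property
    def n_used(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class SiteSummary:
    site_id: str
    n: int
    adj_mean: float
    adj_sd: float  # NaN when n == 1 (undefined-as-missing)


def _design(age: np.ndarray, boy: np.ndarray, age_center: float):
    """Intercept + any non-constant covariate columns.

    Constant columns are dropped (an all-24-month or single-sex sample is
    adjusted by an intercept-only model, i.e. left unchanged), so only a
    genuinely singular non-constant design raises.
    """
    cols = [np.ones_like(age)]
    names = ["intercept"]
    a = age - age_center
    if np.ptp(a) > 0:
        cols.append(a)
        names.append("age_c")
    if np.ptp(boy) > 0:
        cols.append(boy.astype(float))
        names.append("boy")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            "adjustment design is singular (age and sex are collinear)"
        )
    return X, names


def adjust_scores(
    cohort: pd.DataFrame, domain: str, age_center: float = 24.0
) -> AdjustedScores:
    """Adjust one domain's scores for sex and age (centred on 24 months)."""
    if domain not in cohort.columns:
        from .errors import LookupDomainError

        raise LookupDomainError(f"domain {domain!r} not in cohort")
    sub = cohort[["child_id", "site_id", "sex", "age_months", domain]].dropna()
    if len(sub) < 2:
        raise InsufficientDataError(
            f"domain {domain!r}: {len(sub)} complete case(s), need >= 2"
        )
    age = sub["age_months"].to_numpy(dtype=float)
    boy = (sub["sex"].to_numpy() == "boy").astype(float)
    y = sub[domain].to_numpy(dtype=float)

    X, names = _design(age, boy, age_center)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta

    boy_frac = float(boy.mean())
    coefs = dict(zip(names, beta.tolist()))
    # prediction at (age = age_center, boy-share = pooled fraction)
    ref_pred = coefs.get("intercept", 0.0) + coefs.get("boy", 0.0) * boy_frac
    adjusted = resid + ref_pred

    return AdjustedScores(
        domain=domain,
        values=pd.Series(adjusted, index=sub["child_id"].to_numpy(), name=domain),
        site_id=pd.Series(
            sub["site_id"].to_numpy(), index=sub["child_id"].to_numpy(), name="site_id"
        ),
        reference_age=age_center,
        reference_boy_fraction=boy_frac,
        coefficients=coefs,
    )


def site_summaries(
    adjusted: AdjustedScores,
) -> tuple[list[SiteSummary], SiteSummary]:
    """Per-site mean/SD of adjusted values plus the pooled summary.

    The pooled mean and SD are computed over all children together (not as a
    mean of site means); SDs use the n-1 denominator. A site with no
    complete cases simply does not appear (logged as a warning upstream of
    SSD, where the cell is dropped).
    """
    vals = adjusted.values
    sites = adjusted.site_id
    out: list[SiteSummary] = []
    for site, v in vals.groupby(sites, sort=True):
        n = int(v.size)
        sd = float(v.std(ddof=1)) if n > 1 else float("nan")
        out.append(SiteSummary(site_id=str(site), n=n, adj_mean=float(v.mean()), adj_sd=sd))
    pooled = SiteSummary(
        site_id="__pooled__",
        n=int(vals.size),
        adj_mean=float(vals.mean()),
        adj_sd=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
    )
    return out, pooled


def dropped_sites(cohort: pd.DataFrame, adjusted: AdjustedScores) -> list[str]:
    """Sites present in the cohort but absent from the complete cases."""
    all_sites = set(cohort["site_id"].astype(str))
    kept = set(adjusted.site_id.astype(str))
    gone = sorted(all_sites - kept)
    for s in gone:
        logger.warning(
            "site %s has no complete cases for domain %s; cell dropped",
            s,
            adjusted.domain,
        )
    return gone
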