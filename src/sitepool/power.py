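"""Monte-Carlo power for detecting a between-site variance component.

Each replicate draws a balanced one-way Gaussian layout: fresh site effects
u_i ~ Normal(0, s2_b) (with few sites these are the dominant noise source and
are deliberately redrawn every replicate) and residuals with variance s2_w,
scaled so that s2_b / (s2_b + s2_w) equals the target between-site fraction
and the total variance is 1. H0: s2_b = 0 is tested either by

* ``anova_f`` — the one-way ANOVA F test (exact under the null), or
* ``lrt_chibar`` — the likelihood-ratio statistic referred to the boundary
  mixture 0.5*chi2_0 + 0.5*chi2_1. For the balanced layout the ML fit has a
  closed form (see below), so no iterative optimisation is needed. The
  mixture reference is asymptotic in the number of sites and is conservative
  when sites are few.

Closed-form balanced ML: with a sites and n children per site, the profile
log-likelihood separates into a within term (SSW, N - a degrees of freedom)
and a between term (SSB, a site means); the unconstrained maximisers are
s2_w = SSW/(N-a) and tau = s2_w + n*s2_b = SSB/a. If tau < s2_w the
constrained maximum is on the boundary s2_b = 0 and the LRT statistic is 0.

Replicates are generated from a single seeded stream of standard normals
scaled by the target variances, so two calls with the same seed and design
share their randomness (common random numbers) — power comparisons across
between-site fractions are then monotone in the effect, not noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError

__all__ = ["PowerResult", "simulate_power", "power_curve"]


@dataclass(frozen=True)
class PowerResult:
    pct_between: float
    n_sites: int
    n_per_site: int
    alpha: float
    n_reps: int
    test: str
    power: float
    mc_se: float
    seed: int


def _validate(pct_between, n_sites, n_per_site, alpha, n_reps, test):
    if test not in ("lrt_chibar", "anova_f"):
        raise ConfigurationError(
            f"test: expected 'lrt_chibar' or 'anova_f', got {test!r}"
        )
    if not (0.0 <= pct_between < 100.0):
        raise ConfigurationError("pct_between: must be in [0, 100)")
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError("alpha: must be in (0, 1)")
    if n_reps < 100:
        raise ConfigurationError("n_reps: must be >= 100")
    if n_sites < 2 or n_per_site < 2:
        raise ConfigurationError("design: need n_sites >= 2 and n_per_site >= 2")


def _sums_of_squares(rng, pct_between, n_sites, n_per_site, n_reps, chunk=2_000_000):
    """Per-replicate (SSW, SSB) for the balanced layout, chunked for memory."""
    s2b = pct_between / 100.0
    s2w = 1.0 - s2b
    ssw = np.empty(n_reps)
    ssb = np.empty(n_reps)
    per_rep = n_sites * n_per_site
    step = max(1, chunk // per_rep)
    done = 0
    while done < n_reps:
        b = min(step, n_reps - done)
        zu = rng.standard_normal((b, n_sites))
        ze = rng.standard_normal((b, n_sites, n_per_site))
        y = np.sqrt(s2b) * zu[:, :, None] + np.sqrt(s2w) * ze
        site_mean = y.mean(axis=2)
        grand = site_mean.mean(axis=1)
        ssw[done : done + b] = ((y - site_mean[:, :, None]) ** 2).sum(axis=(1, 2))
        ssb[done : done + b] = n_per_site * ((site_mean - grand[:, None]) ** 2).sum(axis=1)
        done += b
    return ssw, ssb


def _reject_anova_f(ssw, ssb, n_sites, n_per_site, alpha):
    N = n_sites * n_per_site
    F = (ssb / (n_sites - 1)) / (ssw / (N - n_sites))
    crit = stats.f.isf(alpha, n_sites - 1, N - n_sites)
    return F > crit


def _reject_lrt_chibar(ssw, ssb, n_sites, n_per_site, alpha):
    N = n_sites * n_per_site
    s2w = ssw / (N - n_sites)
    tau = ssb / n_sites
    interior = tau > s2w
    # deviance difference only where the unconstrained optimum is feasible
    s2_null = (ssw + ssb) / N
    with np.errstate(divide="ignore", invalid="ignore"):
        l1 = -0.5 * ((N - n_sites) * np.log(s2w) + n_sites * np.log(tau) + N)
    l0 = -0.5 * (N * np.log(s2_null) + N)
    T = np.where(interior, 2.0 * (l1 - l0), 0.0)
    crit = stats.chi2.isf(2.0 * alpha, 1) if alpha < 0.5 else 0.0
    return T > crit


def simulate_power(
    pct_between: float,
    n_sites: int,
    n_per_site: int,
    alpha: float = 0.05,
    n_reps: int = 2000,
    test: str = "lrt_chibar",
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power (rejection fraction) at one design point."""
    _validate(pct_between, n_sites, n_per_site, alpha, n_reps, test)
    rng = np.random.default_rng(seed)
    ssw, ssb = _sums_of_squares(rng, pct_between, n_sites, n_per_site, n_reps)
    if test == "anova_f":
        rej = _reject_anova_f(ssw, ssb, n_sites, n_per_site, alpha)
    else:
        rej = _reject_lrt_chibar(ssw, ssb, n_sites, n_per_site, alpha)
    power = float(rej.mean())
    mc_se = float(np.sqrt(power * (1.0 - power) / n_reps))
    return PowerResult(
        pct_between=float(pct_between),
        n_sites=int(n_sites),
        n_per_site=int(n_per_site),
        alpha=float(alpha),
        n_reps=int(n_reps),
        test=test,
        power=power,
        mc_se=mc_se,
        seed=int(seed),
    )


def power_curve(
    pct_between_grid,
    n_sites: int,
    n_per_site: int,
    alpha: float = 0.05,
    n_reps: int = 2000,
    test: str = "lrt_chibar",
    seed: int = 0,
) -> list[PowerResult]:
    """Power along a grid of between-site fractions with common random
    numbers (the same seed, hence the same underlying normals, at every grid
    point)."""
    return [
        simulate_power(p, n_sites, n_per_site, alpha, n_reps, test, seed)
        for p in pct_between_grid
    ]
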