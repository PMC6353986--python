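import numpy as np
import pandas as pd
import pytest

import sitepool as sp


@pytest.fixture(scope="session")
def study_cohort():
    """Study-shaped cohort: 5 sites, 1307 children, 16 domains."""
    return sp.generate_cohort(sp.default_study_config(seed=12345))


@pytest.fixture(scope="session")
def small_config():
    """A light 3-site config with two domains for fast unit tests."""
    return sp.GeneratorConfig(
        site_sizes=(40, 50, 30),
        domains=(
            sp.DomainSpec(name="score_a", beta_age=0.5, beta_sex=1.0, pct_between_target=10.0),
            sp.DomainSpec(name="score_b", pct_between_target=0.0),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sp.generate_cohort(small_config)


def two_site_toy():
    """Balanced 2-site toy A={0,2}, B={4,6} with constant covariates."""
    return pd.DataFrame(
        {
            "child_id": ["a", "b", "c", "d"],
            "site_id": ["A", "A", "B", "B"],
            "sex": ["girl"] * 4,
            "age_months": [24.0] * 4,
            "score": [0.0, 2.0, 4.0, 6.0],
        }
    )


def anova_variance_components(y, groups):
    """One-way ANOVA closed form for balanced REML, truncated at 0.

    Interior (MSB >= MSW): s2b = (MSB - MSW)/n, s2w = MSW. At the boundary
    the constrained REML maximum pools everything: s2b = 0,
    s2w = SST/(N - 1).
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    a = len(labels)
    counts = np.array([(groups == g).sum() for g in labels])
    assert len(set(counts)) == 1, "oracle requires a balanced design"
    n = counts[0]
    means = np.array([y[groups == g].mean() for g in labels])
    grand = y.mean()
    ssb = n * ((means - grand) ** 2).sum()
    ssw = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum() for g in labels)
    msb = ssb / (a - 1)
    msw = ssw / (len(y) - a)
    if msb >= msw:
        return (msb - msw) / n, msw
    return 0.0, (ssw + ssb) / (len(y) - 1)
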