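# sitepool

Can child-level data collected at several study sites be pooled into a single
international standard? `sitepool` implements the statistical machinery used
to answer that question for multi-site studies of early child development
(continuous developmental scores measured around 2 years of age at a handful
of geographically diverse sites), and a synthetic cohort generator with known
ground truth so the whole pipeline is testable without access to any
restricted study data.

## The statistics

**Between-site variance fraction.** Each outcome is modelled with a random
site intercept,

    y_ij = x_ij' beta + u_i + e_ij,    e_ij ~ N(0, sigma2_w),

with covariates (sex, age at assessment centred on 24 months, optionally
fetal and 2-year growth z-scores) as fixed effects. The quantity of interest
is the intraclass correlation expressed as a percentage,

    pct_between = 100 * sigma2_b / (sigma2_b + sigma2_w),

the share of total variance attributable to differences *between* sites
rather than between children within a site. Two families are available for
the site effect `u_i`:

* **Gaussian** (`fit_gaussian_lmm`): `u_i ~ N(0, sigma2_b)`, fitted by ML or
  REML. The likelihood is profiled to one dimension (the variance ratio
  `sigma2_b / sigma2_w`), for which the GLS fixed effects and residual
  variance are closed-form, so the optimum — including the `sigma2_b = 0`
  boundary — is found exactly by a bounded 1-D search.
* **Nonparametric maximum likelihood** (`fit_npml`): the distribution of
  `u_i` is an estimated discrete set of K mass points (locations theta_k,
  probabilities pi_k), fitted jointly with the fixed effects by EM;
  `sigma2_b` is the mass-point variance. `K='auto'` selects K by BIC.
  Competing fits are ranked with `compare_models` by AIC/BIC.

**Standardised site differences (SSD).** For each domain, child-level scores
are adjusted by a single pooled regression on sex and age (centred on
24 months), and each site is summarised by

    SSD_i = (adjusted site mean_i − pooled adjusted mean) / pooled SD.

Sites with |SSD| ≤ 0.5 (a closed band) are considered compatible with
pooling. Comparisons are organised into a primary item set (9 items: 7
directly assessed/observed domains plus two gross-motor milestone ages) and
a secondary set (7 language/behaviour domains), giving 45 + 35 = 80
comparisons for a five-site study.

**Power.** `simulate_power` estimates Monte-Carlo power to detect a nonzero
between-site fraction in a balanced one-way design, using either the exact
one-way ANOVA F test or the likelihood-ratio test against the boundary
mixture 0.5·chi2(0) + 0.5·chi2(1).

**Flow accounting.** `flow_summary` performs the deterministic participant
flow arithmetic (eligible → seen → assessed → analysed) with half-up
percentage rounding; the five-site study flow (1753 → 1422 → 1339 → 1307,
an average of 261 children per site) ships as `sitepool.STUDY_FLOW` and
`examples/flow.yaml`.

## Worked example

```python
import sitepool as sp

cfg = sp.default_study_config(seed=20)      # 5 sites, 1307 children, 16 domains
cohort = sp.generate_cohort(cfg)

fit = sp.fit_gaussian_lmm(cohort, "emotional_reactivity", "age_sex", method="reml")
print(f"REML: {fit.pct_between:.1f}% of total variance between sites "
      f"(truth {sp.true_variance_fraction(cfg, 'emotional_reactivity'):.1f}%)")

vd, mp = sp.fit_npml(cohort, "emotional_reactivity", "age_sex", K="auto")
print(f"NPML: {vd.pct_between:.1f}% between sites, K={mp.K} mass points, BIC={vd.bic:.1f}")

table, report = sp.poolability_analysis(cohort)
print(report.summary())
for r in report.outside_band:
    print(f"  outside: {r.domain} at {r.site_id}: SSD {r.ssd:+.2f}")

res = sp.simulate_power(10.0, n_sites=5, n_per_site=261, test="anova_f", seed=1)
print(f"power at 10% between-site variance: {res.power:.3f} (MC SE {res.mc_se:.3f})")
```

prints

```
REML: 10.9% of total variance between sites (truth 14.2%)
NPML: 9.4% between sites, K=3 mass points, BIC=9659.9
Equivalence band: +/-0.5 pooled SD (closed)
  primary: 0 of 45 comparisons outside the band
  secondary: 3 of 35 comparisons outside the band -> review before pooling
  total comparisons: 80
  outside: expressive_language at site2: SSD +0.59
  outside: expressive_language at site4: SSD -0.53
  outside: emotional_reactivity at site5: SSD -0.61
power at 10% between-site variance: 0.989 (MC SE 0.002)
```

The single-replicate REML estimate (10.9% vs a 14.2% truth) illustrates why
a five-site design identifies the between-site fraction only coarsely — the
realised spread of five site effects is itself random. The generator's
`fix_site_effects` option pins the realised between-site variance to the
target exactly, which is what the recovery tests use. The two emotional
reactivity / expressive language domains are generated with the largest
between-site fractions (14.2% / 7.3%), and they are the ones that produce
SSD values outside the ±0.5 band.

The same steps are available from a shell:

```sh
sitepool simulate --seed 3 --out cohort.csv
sitepool varcomp  --in cohort.csv --domain cognitive --method all --out vc.json
sitepool table3   --in cohort.csv --method npml --out table.csv
sitepool ssd      --in cohort.csv --out-csv ssd.csv --out-report report.json
sitepool power    --pct-between 10 --sites 5 --n-per-site 261 --test anova_f
sitepool flow     --counts examples/flow.yaml
```

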