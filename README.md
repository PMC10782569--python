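# prevdecomp

Design-weighted prevalence trends, demographic decomposition, and two-level
random-intercept logistic modelling for multi-wave health surveys.

The package implements the computational core of a common epidemiological
study design: tracking a binary indicator (the motivating application is
recent HIV testing among women across the 2006, 2012 and 2016/17 Haiti
Demographic and Health Surveys), asking *how much* it changed between
survey waves, *why* it changed (shifting population composition versus
shifting group behavior), and *which* individual- and community-level
factors are associated with it once the clustered two-stage sample design
is taken into account.

## What it computes

**Weighted prevalence and trends** (`prevdecomp.survey`).  The prevalence
is the ratio estimator p̂ = Σwᵢyᵢ / Σwᵢ; its variance comes from Taylor
linearization with clusters as primary sampling units within strata, and
95% CIs are built on the logit scale.  Association screens use the
Rao-Scott second-order corrected chi-square, which stays calibrated under
cluster sampling where the plain Pearson test grossly over-rejects.

**Kitagawa decomposition** (`prevdecomp.decomposition`).  Writing the
national prevalence as Y_t = Σⱼ ω_jt y_jt over subgroups j, the change
between waves splits exactly into

    ΔY = Σⱼ Δωⱼ ȳⱼ   +   Σⱼ ω̄ⱼ Δyⱼ
         (compositional)   (behavioral)

with midpoint weights ȳⱼ = (y_j,t+1 + y_j,t)/2 and ω̄ⱼ likewise.  The
behavioral part can be refined by regressing subgroup rates on a scored
covariate within each wave, splitting each group's change into intercept,
covariate-level, slope and residual terms — again an exact identity.

**Multilevel models** (`prevdecomp.multilevel`).  A two-level
random-intercept logistic regression, logit P(y=1) = x'β + u_c with
u_c ~ N(0, σ²ᵤ), fitted by maximizing the marginal likelihood with
adaptive Gauss-Hermite quadrature.  The standard four-model ladder (null,
individual-level, community-level, full) is reported with the cluster
variance, the latent-scale ICC = σ²ᵤ/(σ²ᵤ + π²/3), the proportional change
in variance PCV = (V_null − V_model)/V_null, log-likelihood, AIC, and a
VIF collinearity screen.

**Synthetic survey data** (`prevdecomp.synthetic`).  A seeded generator of
stratified two-stage microdata (strata = region × residence, clusters
within strata, Poisson-perturbed cluster sizes, inverse-selection
weights) whose outcome follows the random-intercept model with known
ground truth — the basis for the package's parameter-recovery and
calibration tests.  `preset_haiti_margins()` is calibrated to the
published education/age compositions and group prevalences of the
motivating surveys.

## Worked example

The published per-wave totals and group margins ship with the package, so
the headline numbers can be re-derived in a few lines:

```python
from prevdecomp.datasets import haiti_totals, group_summaries_from_margins
from prevdecomp.survey import counts_frame, weighted_prevalence, prevalence_ratio, relative_change
from prevdecomp.decomposition import decompose_summaries
from prevdecomp.multilevel import icc, pcv, aic

totals = haiti_totals()
frame = counts_frame({r.wave: (r.tested, r.not_tested) for r in totals.itertuples()})
est = {w: weighted_prevalence(frame, (frame["wave"] == w).to_numpy(), domain_label=w)
       for w in ("2006", "2012", "2016-17")}
for w, e in est.items():
    print(f"{w}: {100*e.p_hat:.1f}% (95% CI {100*e.ci_low:.1f}-{100*e.ci_high:.1f})")
print("ratio 2016-17 vs 2006:", round(prevalence_ratio(est["2016-17"], est["2006"]), 2))
print("decline 2012 -> 2016-17:", round(relative_change(est["2012"], est["2016-17"]), 1), "%")

r = decompose_summaries(group_summaries_from_margins("education", "2006"),
                        group_summaries_from_margins("education", "2016-17"))
print(f"compositional {r.compositional_share:.1f}% / behavioral {r.behavioral_share:.1f}%")
print("ICC(0.74) =", round(100*icc(0.74), 2), "%;  PCV:", round(pcv(0.74, 0.49), 2),
      "%;  AIC:", aic(-2459.97, 2))
```

prints

```
2006: 8.8% (95% CI 8.2-9.4)
2012: 24.1% (95% CI 23.3-24.9)
2016-17: 21.3% (95% CI 20.6-22.1)
ratio 2016-17 vs 2006: 2.42
decline 2012 -> 2016-17: 11.6 %
compositional 17.5% / behavioral 82.5%
ICC(0.74) = 18.36 %;  PCV: 33.78 %;  AIC: 4923.94
```

Testing prevalence rose from 8.8% to 21.3% — more than twofold — with an
11.6% relative dip after 2012; only 17.5% of the 2006→2016/17 rise is
explained by the changing education composition, the rest by rising
testing within education groups; and in 2006 about 18% of the latent
outcome variance sat between sampling clusters, a third of which the full
covariate set explains.

A command-line interface covers the same ground on record-level CSVs:

```
prevdecomp simulate --preset haiti-margins --seed 7 --out records.csv
prevdecomp prevalence records.csv --schema schema.yaml
prevdecomp decompose records.csv --schema schema.yaml --from 2006 --to 2016-17 --by education
prevdecomp run --preset haiti-margins --seed 7 --out results/
```

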