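# quantgap

Counterfactual quantile-regression decomposition of between-group health
disparities, with a layer that maps the results onto population-health
intervention strategies.

## The problem

Mean-based disparity analyses (Blinder–Oaxaca and relatives) answer *how
much* of an average gap between two social groups is explained by observed
risk factors. They say nothing about *where in the outcome distribution*
the gap lives, or whether the two groups respond to the same risk factors
in the same way. Both questions matter when choosing between
**proportionate universalism** (universal action with intensity
proportional to disadvantage — appropriate when groups respond alike but
carry different risk levels) and a **targeted approach** (group-specific
intervention — needed when the risk–outcome mechanisms themselves differ).

`quantgap` implements the quantile-regression-based counterfactual
decomposition (Machado–Mata / Chernozhukov-style) for exactly this
purpose. For each group *g* it estimates a linear conditional quantile
process

&nbsp;&nbsp;&nbsp;&nbsp;*Q*<sub>y</sub>(τ | x, g) = x′β̂<sub>g</sub>(τ),&nbsp;&nbsp;τ ∈ (0, 1),

by minimising the check loss ρ<sub>τ</sub>(u) = u(τ − 1[u&lt;0]). Marginal
quantile functions are built by pooling the prediction surface
x<sub>i</sub>′β̂<sub>j</sub>(τ<sub>m</sub>) over a covariate sample and a
dense τ grid; the counterfactual *Q*⟨ref|cmp⟩ combines the reference
(advantaged) group's coefficients with the comparison group's covariates.
The gap at each reported quantile splits exactly:

- **difference**(τ) = *Q*<sub>ref</sub>(τ) − *Q*<sub>cmp</sub>(τ)
- **covariates part** = *Q*<sub>ref</sub>(τ) − *Q*⟨ref|cmp⟩(τ) — composition
  of risk-factor levels → proportionate universalism can act here
- **coefficients part** = *Q*⟨ref|cmp⟩(τ) − *Q*<sub>cmp</sub>(τ) —
  heterogeneous responses → targeted approach needed

Pointwise confidence intervals come from a within-group percentile
bootstrap that re-runs the whole pipeline on every replicate. A detailed
(per-covariate) breakdown flags *countervailing* covariates — those whose
level gap closes the disparity while the response gap would blunt a
level-raising intervention — and a strategy report classifies every
reported quantile.

Because the motivating survey data are restricted, the package ships a
synthetic-data module generating two-group location-scale populations
(y = x′β + (x′γ)ε) with income-, network-, support- and literacy-like
covariates and *known* true decompositions via closed forms and a
Monte-Carlo oracle, so every pipeline stage is testable end to end.

## Worked example

```python
import numpy as np
from quantgap import AnalysisSpec, decompose_gap, make_paper_like_fixture

ref, cmp_, truth = make_paper_like_fixture(seed=1)   # 575 + 249 subjects
spec = AnalysisSpec(
    outcome_name="intake", group_name="education",
    reference_level="reference", comparison_level="comparison",
    covariate_names=("income", "network", "support", "literacy"),
    bootstrap_reps=100, seed=1,
)
dec = decompose_gap(ref, cmp_, spec)
cols = ["difference", "covariates_part", "coefficients_part", "coefficients_pct"]
summary = dec.summary()[["tau", *cols, "indication"]].round(dict.fromkeys(cols, 1))
print(summary.to_string(index=False))
```

prints

```
 tau  difference  covariates_part  coefficients_part  coefficients_pct indication
0.10        25.7              2.3               23.4              90.9   combined
0.25        25.0              2.7               22.3              89.4   combined
0.50        27.6              3.1               24.5              88.8   combined
0.75        30.5              3.5               27.0              88.4   combined
0.90        36.2              3.5               32.7              90.4   combined
```

Read: the gap in energy-adjusted intake grows from ≈ 26 to ≈ 36 units
across the outcome distribution; ≈ 90% of it is attributable to different
covariate–outcome responses (coefficients part), so targeted intervention
dominates, while the covariates part — though small — is itself
significant at every quantile, so a proportionate-universalist component
applies alongside it (`combined`). The attached `truth` object carries
the generator's exact decomposition (true median difference 29.9, true
coefficients part 23.8) for comparison with the estimates.

The same pipeline runs from the shell on any delimited file:

```bash
quantgap fixture --out fixture.csv --seed 1
quantgap decompose --input fixture.csv --outcome intake --group education \
    --reference-level reference --comparison-level comparison \
    --covariates income,network,support,literacy --bootstrap 100 \
    --seed 1 --outdir out/
```

which writes the decomposition table, per-group coefficient tables, the
per-covariate detail table, the strategy report (JSON + text), a kernel
density summary and a run manifest.

Estimator classes (`ProcessQuantileRegressor`, `QuantileGapDecomposer`)
follow scikit-learn conventions (`fit`, `get_params`, fitted attributes
with trailing underscores) and compose with sklearn tooling.

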