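# spermarche

**When do male alpacas start producing sperm?** Tools for modelling the
onset of sperm production (spermarche) in alpacas (*Vicugna pacos*) from
testicular length, age and body condition score — the measurements a
veterinarian or breeder can actually take in the field.

Puberty in male alpacas is reported anywhere between 1 and 3 years of
age, which makes husbandry decisions (separating sexes, selecting sires,
timing castration) hard to schedule by age alone. This package
implements the statistical machinery for basing those decisions on
testicular length instead:

* **Growth model.** Mean testicular length *L*ᵢ (cm, the average of the
  left and right testicle) is modelled as
  *L*ᵢ ~ Normal(*μ*ᵢ, σ) with a logistic growth curve in age,

  *μ*ᵢ = α / (1 + e^(−β(Ageᵢ − γ))),

  where α is the asymptotic maximum length (cm), β the increment rate
  (per month) and γ the inflection age (months). A body-condition
  variant multiplies the exponent by BCSᵢ·δ, so condition rescales the
  increment rate; in that variant β is held at its posterior mode from
  the plain fit. Posteriors are sampled by an adaptive random-walk
  Metropolis algorithm; variants are compared against an intercept-only
  null model by DIC (deviance information criterion,
  DIC = D̄ + p_D with p_D = D̄ − D(θ̄)).

* **Sperm-presence model.** For excised organ pairs (castration or
  necropsy material) with a verified sperm outcome, binomial-logit GLMs
  of sperm presence on age or on mean length are fitted and compared by
  AIC, Wald p-values and pseudo-R² (McFadden, Nagelkerke, Tjur). The
  fitted length curve is inverted into two management cut-offs: the
  length where the probability of sperm presence reaches 0.99
  (production near-certain) and 0.01 (near-impossible).

* **Descriptive tables** binned by length (<3, 3–3.9, >4 cm) and age
  group, with sperm-presence percentages.

* **Synthetic cohorts.** The field data behind the original study were
  never deposited, so a seeded generator simulates cohorts from the
  generative model above — including a 72-animal on-farm design (ages
  13–48 months, BCS 2.5–5, calliper measurements that include the
  scrotal layers) and a 28-organ excised design (22 castrations + 6
  necropsies, ages 11–113 months) — plus deterministic fixtures whose
  binned margins reproduce the published summary tables cell for cell.

## Worked example

```python
import warnings
from spermarche import (
    MCMCConfig, compare_predictors, cross_tabulate, experiment1_config,
    fit_model, simulate_cohort, table_fixture,
)

# Published on-farm length-by-age table, reproduced by the fixture
print(cross_tabulate(table_fixture("experiment1")).render_text())

# Bayesian growth fit on a simulated 72-animal cohort
cohort = simulate_cohort(experiment1_config(seed=1, in_vivo_offset_cm=0.0))
mc = MCMCConfig(n_chains=2, n_iterations=10_000, n_burnin=3_000, seed=1)
null = fit_model(cohort, "null", config=mc)
inc = fit_model(cohort, "increment", config=mc, reference=null)
for name, s in inc.summaries.items():
    print(name, s.formatted(3))
print(f"DIC {inc.dic:.2f} (delta vs null {inc.delta_dic:.2f})")

# Sperm-presence comparison and thresholds on the excised-organ fixture
cmp_ = compare_predictors(table_fixture("experiment2"))
print(cmp_.preferred, cmp_.thresholds.lower_rounded, cmp_.thresholds.upper_rounded)
```

prints

```
Mean length (cm)  12–23 months  24–35 months  36–48 months  Total
<3                8             –             –             8
3–3.9             14            8             –             22
>4                8             24            10            42
Total             30            32            10            72

alpha 5.808 (4.814–8.623)
beta  0.038 (0.021–0.077)
gamma 6.654 (0.867–33.970)
sigma 0.268 (0.225–0.324)
DIC 5.20 (delta vs null 107.82)

mean_length_cm 1.5 4.3
```

The growth curve decisively beats the constant-mean model (ΔDIC ≈ 108
on this cohort), the credible intervals bracket the generating values
(α = 4.96, β = 0.078, γ = 5.89, σ = 0.3) — wide for β and γ because a
13–48-month cohort pins the inflection and asymptote only loosely — and
on the organ fixture sperm presence is better explained by length
(AIC 24.4) than age (AIC 30.0), with sperm production near-certain above
4.3 cm and near-impossible below 1.5 cm for that cohort.

## Command line

```
spermarche simulate  --seed 1 --out cohort.csv
spermarche fixture   --table experiment2 --out organs.csv
spermarche tabulate  --cohort cohort.csv --scheme experiment1
spermarche fit-growth --cohort cohort.csv --variant increment --out growth.json
spermarche fit-sperm --cohort organs.csv --bootstrap 2000 --seed 1 --out sperm.json
spermarche run-all   --simulate experiment1 --seed 1 --out report.json
```

Cohorts travel as plain CSV
(`animal_id,source,age_months,bcs,left_length_cm,right_length_cm,mean_length_cm,sperm_present`);
results are JSON.

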