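# synthctrl

Synthetic-control policy evaluation for annual, one-treated-unit panels —
the comparative-case-study setting in which a single region (a city, a
province) adopts a policy and a dozen untreated peers are available as a
donor pool. The motivating application is the evaluation of a public-hospital
drug pricing reform piloted in one prefecture-level city, where the outcome
is the drug share of per-visit medical cost (in percentage points) and the
question is how much the reform lowered it.

The package provides, as scikit-learn-style estimators:

- **`SyntheticControl`** — the counterfactual is a convex combination of
  donors, `Ŷ₁ₜᴺ = Σⱼ wⱼ Yⱼₜ` with `wⱼ ≥ 0`, `Σ wⱼ = 1`. Weights minimize
  the matching distance `(X₁ − X₀W)′ V (X₁ − X₀W)` over predictors built
  from pre-policy covariate means and outcome lags; the diagonal importance
  matrix `V` is chosen by a nested optimization that minimizes the
  pre-policy outcome MSPE of the implied synthetic unit. The policy effect
  in year `t` is the gap `α̂₁ₜ = Y₁ₜ − Ŷ₁ₜᴺ`.
- **`PlaceboTest`** — in-space permutation inference: treatment is
  reassigned to every donor in turn, the estimator is refit identically, and
  the treated unit's mean post-policy gap is ranked against the placebo
  distribution. Placebos whose pre-policy MSPE exceeds 5× the treated
  unit's are excluded as lacking fit before the pseudo p-value is computed.
- **`DifferenceInDifferences`** — the cross-check regression
  `Y_it = γ + β₁Treat_i + β₂Post_t + β₃Treat_i·Post_t + bX_it + ε_it`,
  with the interaction `β₃` as the effect estimate.

A donor-level adjustment (`adjust_donor_level`) handles the case where the
treated unit sits at a persistently different outcome level than every
donor (so no convex combination can match it): donor outcomes are shifted by
a fixed number of percentage points, recorded in provenance. A factor-model
panel generator (`synthctrl.simulate`) produces study-scale panels with
known ground truth, so every estimator is testable without external data.

## Worked example

Generate a study-scale panel (13 cities, 2008–2015, policy in 2013, true
effect −7.7 pp) and fit the synthetic control:

```bash
synthctrl simulate --scenario outpatient-like --seed 2 --out demo/panel.csv
synthctrl fit --panel demo/panel.csv --treated treated --policy-year 2013 \
    --outcome drug_share --v-mode auto --seed 2 --out demo/fit
```

`demo/fit/summary.json` then contains (abridged):

```json
{
  "effect": {
    "mean_post_gap": -8.49,
    "baseline_year": 2012,
    "baseline_level": 45.32,
    "relative_effect": 18.7
  },
  "pre_mspe": 0.119
}
```

The synthetic city tracks the treated city to within a pre-policy MSPE of
0.12 pp², and the post-policy gap averages −8.5 pp — the estimate of the
reform effect, 18.7% of the 2012 baseline level (the true simulated effect
is −7.7 pp; the difference is one draw's noise). `weights.csv` shows the
counterfactual is built almost entirely from one donor (w = 0.931) whose
latent trend matches the treated city.

Inference, from Python:

```python
import synthctrl as sc

panel = sc.load_panel("demo/panel.csv", treated_unit="treated",
                      policy_year=2013, outcome="drug_share")
placebo = sc.run_placebo(panel, v_mode="equal")
print(placebo.pseudo_p)        # 0.0  — no retained placebo as extreme
print(placebo.excluded_units)  # ['donor09', 'donor10', 'donor12'] (poor fit)

did = sc.fit_did(panel)
print(did.beta3, did.ci95)     # -7.94 (-10.59, -5.29) — cross-validates SCM
```

A pseudo p-value of 0 means no placebo city, refit under the identical
specification, shows a post-policy divergence as large as the treated
city's. The full pipeline (adjust → fit → placebo → DiD → report bundle) is
driven by one YAML config through `synthctrl report --config study.yaml`.

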