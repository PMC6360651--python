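# proxfert

Proximate-determinants-of-fertility decomposition toolkit. The total
fertility rate (TFR) is modelled as the product of four
fertility-inhibiting indices applied to a biological maximum (total
fecundity, TF = 15.3 by default):

```
TFR = Cm * Cc * Cfw * Ci * TF
```

where

- **Cm** (marriage) — fertility-weighted mean of the proportions of
  women in union by five-year age group: `Cm = Σ m(a)g(a) / Σ g(a)`;
- **Cc** (contraception) — `Cc = 1 − 1.08·u·e`, with prevalence `u`
  among in-union women and use-effectiveness-weighted mean `e`
  (pill 0.90, IUD 0.95, sterilization 1.00, injection 0.99, other 0.70);
- **Ci** (postpartum infecundability) — `Ci = 20 / (18.5 + i)` for a
  mean postpartum-amenorrhea duration of `i` months;
- **Cfw** (foetal wastage) — `Cfw = TFR / (TFR + AFW)` with
  `AFW = 0.4·(1 + u)·TFW` births averted per woman.

The package computes these indices from aggregate inputs or from a flat
woman-level survey table, decomposes fertility into percent inhibition
per determinant, stratifies by background covariates (region, wealth
quintile, education, residence), projects the TFR under
contraceptive-prevalence scenarios, and ships a synthetic-population
generator whose implied indices are known in closed form for end-to-end
validation.

## Library quick start

```python
import proxfert as pf

# aggregate mode: compose and decompose published index values
tfr = pf.compose_tfr(cm=0.656, cc=0.693, ci=0.655, cfw=0.908)   # 4.137
pf.percent_inhibition(0.656)                                    # 34.4

# projection under a contraception-only change
s = pf.ProjectionScenario(tfr1=4.6, u1=0.36, e1=0.933, u2=0.55, e2=0.933)
pf.project_tfr(s)                                               # 3.22

# microdata mode
df = pf.read_women_csv("pop.csv")
bundle = pf.estimate_indices(df, window=pf.EstimationWindow(3.0))
result = pf.stratified_analysis(df, "residence")

# synthetic populations with known ground truth
spec = pf.PopulationSpec.from_target_indices(
    cm=0.656, cc=0.693, ci=0.655, cfw=0.908, tfr_obs=4.14, n=15_000
)
pop = pf.simulate_population(spec, seed=42)
pf.implied_indices(spec)      # exact targets
pf.estimate_indices(pop)      # recovered within sampling error
```

The woman-level CSV schema is documented in
`src/proxfert/estimators.py` (columns `age_group`, `in_union`,
`births_in_window`, `method`, `amenorrhea_months`, `wastage_in_window`,
the four stratum variables, and an optional `weight`).

## CLI

Installed as `pdf`:

```bash
pdf simulate --spec spec.yaml --seed 42 --out pop.csv
pdf indices pop.csv --out indices.json            # microdata mode
pdf indices --cm 0.656 --cc 0.693 --ci 0.655 --cfw 0.908   # aggregate mode
pdf stratify pop.csv --by region --format csv --out by_region.csv
pdf project --tfr1 4.6 --u1 0.36 --u2 0.55 --e 0.933
pdf report indices.json
```

A YAML config (`--config`) can override the effectiveness table, total
fecundity, the 1.08 sterility adjustment, and the reporting rounding
digits (indices 3 dp, stratified TFRs 3 dp, percent inhibition 1 dp,
projections 1 dp; rounding is applied only when reporting, never inside
computation). Simulation specs accept either direct parameters or a
`target_indices` block that is inverted analytically.

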