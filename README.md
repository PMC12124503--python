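# undesired

Toolkit for classifying "undesired" (unwanted) children from fertility
preferences and birth histories, and for modelling under-five morbidity on
DHS-style survey microdata. Because the real survey recode is
access-restricted, the package ships a synthetic population generator with
known ground truth, so every downstream stage is testable end to end.

## What it does

| Module | Purpose |
| --- | --- |
| `undesired.synthdata` | DHS-like population generator: ideal-composition triples (truncated at nine), sequential births with a sex-ratio parameter, independent under-five deaths, covariate blocks, and binary outcomes from a latent multivariate normal; includes an exact enumeration oracle for excess prevalences |
| `undesired.classify` | Undesiredness classification: static mother-level rule and sequential child-level rule (excess in boys / girls / dual / parity), eligibility filters, prevalence aggregation |
| `undesired.descriptives` | Moment summaries (mean/variance/sd/skewness/kurtosis) and prevalence cross-tabulations by excess category and background characteristics |
| `undesired.assoc` | Tetrachoric correlation matrix (ML under the bivariate-normal threshold model), KMO sampling adequacy, Bartlett sphericity, correlation-matrix PCA with scree/contribution outputs and feature selection |
| `undesired.mvprobit` | From-scratch multivariate probit estimated by GHK simulated maximum likelihood with common random numbers; coefficient/correlation report table |
| `undesired.ml` | Random-forest and hand-rolled sigmoid MLP classification with accuracy/sensitivity/specificity and two variable-importance measures (permutation accuracy drop, impurity decrease) |
| `undesired.pipeline` | Orchestration: simulate → filter → classify → tabulate → associate → model → evaluate, with a hashed provenance manifest |

## CLI

```bash
# full pipeline from a YAML config
undesired run --config run.yaml

# individual stages
undesired simulate --n-mothers 2000 --seed 7 --out data/
undesired classify --mothers data/mothers.csv --children data/children.csv --dual-rule sex_and_parity --out out/
undesired validate --mothers data/mothers.csv --children data/children.csv
undesired tables   --config run.yaml --by mage,prov,wealth
undesired pca      --config run.yaml --method tetrachoric --n-keep 5
undesired mvprobit --config run.yaml --outcomes ari,cough,diarrhea,fever,srb --regressors ep,ed,eg,eb,bord,mage --draws 100 --seed 7
undesired ml       --config run.yaml --models rf,nn --seed 7
```

A minimal `run.yaml`:

```yaml
output_dir: out/
seed: 7
sim:
  default: true        # built-in survey-like configuration
  n_mothers: 2000
dual_rule: sex_and_parity
```

Exit codes: 0 ok, 1 configuration error, 2 stage failure.

## Data model

`mothers.csv`: `mother_id, B_m, G_m, N_m, C_m` (ideal boys/girls/either and
their sum) plus covariates (`edu, wealth, resid, prov, mage, wsw, exc_m,
empment, visit_hw`). `children.csv`: `mother_id, birth_order, sex (M/F),
alive (0/1), death_after, age_ch` plus binary morbidity
(`diarrhea, fever, cough, srb, ari`) and treatment (`pnc, vita, tod, tofc`)
flags. DHS-style 1/2 sex codes are remapped with a warning. `death_after`
records the birth order after which a death event occurs (default: the
child's own birth), which the sequential classifier replays.

Two dual-excess readings exist in the source methodology; both are
implemented (`dual_rule`: `sex_and_parity`, the default exercised by the
worked example, or `both_sexes`).

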