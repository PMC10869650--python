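# trialcua

Trial-based cost-utility analysis in Python: from patient-level two-arm RCT
records (resource use plus quality-of-life questionnaires over six scheduled
time points) to incremental costs, QALYs, ICERs, bootstrap cost-effectiveness
planes and acceptability curves — with multiple imputation by predictive mean
matching, Rubin's-rules pooling, GLM family/link selection diagnostics,
cluster-robust inference and a five-variant sensitivity suite.  A synthetic
trial generator reproduces the statistical structure the analysis assumes, so
the whole pipeline runs and is testable without any external data.

## Modules

| Module | What it does |
| --- | --- |
| `trialcua.synthetic_trial` | Deterministic synthetic two-arm multi-centre RCT datasets (latent utilities mapped to EQ-5D-3L items through a monotone threshold ladder, right-skewed resource-use counts, calibrated MAR missingness); long-CSV serialisation with schema validation |
| `trialcua.qol_valuation` | Additive tariff valuation of EQ-5D-3L (UK value set shipped) and condition-specific responses; discounted QALY area-under-the-curve with the surgery-wait adjustment |
| `trialcua.costing` | Component micro-costing of the index surgery, per-period primary/secondary follow-up costs, exact-decimal ledgers, annual discounting and the no-surgery zero-cost rule |
| `trialcua.missing_data` | Missingness logistic diagnostics, proper multiple imputation by predictive mean matching (knn donors), Rubin's rules |
| `trialcua.glm_engine` | GLM fitting with cluster-robust sandwich covariance, modified Park test, Pregibon / modified Hosmer-Lemeshow / Pearson link diagnostics, family/link selection and recycled-prediction incremental means |
| `trialcua.cea` | Cluster bootstrap of the joint incremental distribution, ICER/dominance classification, net monetary benefit, CEACs, sensitivity suite |
| `trialcua.reporting_cli` | `trialcua` command line: `simulate`, `analyse`, `sensitivity`; CSV report tables plus a JSON summary |

## Quick start

```python
import trialcua as t

config = t.TrialConfig(n_per_arm=298, n_centres=21, seed=1)
dataset = t.generate_trial(config)

options = t.AnalysisOptions(m=20, knn=5, n_bootstrap=2000, seed=1)
result = t.analyse(dataset, options)
print(result.delta_cost.estimate, result.delta_qaly.estimate)
print(result.icer, result.probability_cost_effective(20_000))

results, errors = t.run_sensitivity_suite(dataset, options)
print(t.table3_frame(results))
```

## Command line

```bash
trialcua simulate -c config.yaml -o trial.csv          # dataset + JSON sidecar
trialcua analyse  -c config.yaml -d trial.csv -o out/  # full report bundle
trialcua sensitivity -c config.yaml -d trial.csv -o out/
```

`config.yaml` takes `trial:` (TrialConfig fields), `analysis:`
(AnalysisOptions fields) and `paths:` (unit-cost table, tariff, mapping CSVs)
sections; everything has defaults.  The report bundle contains
`table1_costs.csv`, `table2_utilities.csv`, `table3_cea.csv`, `ce_plane.csv`,
`ceac.csv`, `summary.json` and `run.log`.  All randomness flows from the
configured seeds, so identical configurations give byte-identical summaries.

Note the shipped unit-cost table (`trialcua/data/unit_costs_toy.csv`) is a
plausible toy table for testing, not authoritative prices; real analyses
should supply their own CSV.

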