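# hospeval

Composite-indicator performance evaluation for public hospitals: a
three-level indicator hierarchy (4 primary indexes / 11 sub-indexes / 41
leaf indicators) is combined with tendency normalization, AHP + entropy
weighting and a weighted-TOPSIS ranking, and the resulting score is
surrogate-modelled by a single-hidden-layer backpropagation network
(Levenberg–Marquardt training, hidden size selected by leave-one-out
cross-validation) with a PLSR baseline for comparison. Because the original
hospital indicator matrix is not public, a synthetic-data module generates
hospital matrices with the assumed latent-quality structure so the whole
pipeline is testable end to end.

## Layout

| module | role |
| --- | --- |
| `hospeval.indicator_system` | hierarchy types, loading/validation/serialization, comprehensive weights; bundles the published 41-leaf config |
| `hospeval.preprocessing` | tendency treatment: benefit / cost / interval indicators onto a [0, 1] bigger-is-better scale |
| `hospeval.weighting` | AHP priority vectors + consistency ratio, entropy weights, comprehensive-weight assembly |
| `hospeval.topsis` | weighted TOPSIS relative approach degree `C_i` and ranking |
| `hospeval.neural_net` | from-scratch feedforward net (logistic hidden, linear output), min–max scaling, LM / gradient-descent training, MSE/RMSE/R²/MAPE |
| `hospeval.evaluation` | LOOCV driver, hidden-size selection, NIPALS PLSR baseline, error-analysis table |
| `hospeval.synthetic_data` | latent-quality hospital simulator and near-consistent pairwise judgment matrices |
| `hospeval.cli` | `hospeval` command-line front end |
| `hospeval.datasets` | published reference values (TOPSIS scores, PLSR error-analysis pairs) |

## CLI

```bash
hospeval validate-config                       # check the bundled hierarchy
hospeval simulate --seed 42 --out matrix.csv   # synthetic raw matrix
hospeval weights --mode entropy --matrix matrix.csv --out weights.csv
hospeval topsis --matrix matrix.csv --out rank.csv
hospeval train --matrix matrix.csv --seed 1 --hidden 10 --out model.json
hospeval evaluate --matrix matrix.csv --seed 1 --hidden 10 --out results/
hospeval pipeline --seed 1 --out run/          # simulate → weights → topsis → surrogate
hospeval report --out rep/ run/
```

All stochastic stages require `--seed`; rerunning with the same seed
produces byte-identical artifacts.

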