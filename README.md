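# grmcompare

A Monte-Carlo simulation framework comparing three patient-group mean
comparison strategies for multi-item (patient-reported outcome style)
measures under the graded response model (GRM):

* **sum-score** — listwise-deleted sum scores + Welch's t-test,
* **IRT-model** — two-group marginal-ML GRM fits + a df=1 likelihood-ratio
  test of the equal-means constraint,
* **IRT-EAP** — expected-a-posteriori trait scores from pre-calibrated
  (error-perturbed) item parameters + Welch's t-test,

each run with and without an IRT-LRT DIF prescreening step
(all-others-as-anchors scan, rank-based anchor selection, anchored
retest). The simulation design crosses sample size (100/400 per group),
test length (5/20 items), discrimination strength (high/low), response
categories (2/5), threshold spread (homogeneous/diverse), directional DIF
on 40% of items (present/absent), MAR missingness (present/absent), and
a true focal-group mean of 0 or 0.5 — 256 cells in all. Outcomes (Type I
error, power, effect-size MAE) are summarised per condition × method ×
prescreening arm and condensed with shallow regression trees (depth ≤ 4,
zero complexity threshold).

## Layout

| module | contents |
| --- | --- |
| `grmcompare.model` | GRM probabilities, quadrature marginal likelihood, two-group ML estimation under invariance constraint plans, LRT, EAP scoring |
| `grmcompare.simulate` | item banks, condition grid, item/trait draws, DIF injection, response generation, MAR missingness, DTF effect size |
| `grmcompare.compare` | the three comparison approaches and their shared Welch/effect-size machinery |
| `grmcompare.prescreen` | all-others-as-anchors DIF scan, anchor selection, anchored retests |
| `grmcompare.study` | seeded replication runner and the three summary tables |
| `grmcompare.trees` | deterministic CART-style regression trees over summary tables |
| `grmcompare.io` / `grmcompare.cli` | CSV/JSON interfaces and the command line |

## CLI

```bash
# run a slice of the design (450 reps/cell is the full-scale default)
grmcompare simulate --cells "dif=present;n_items=5" --reps 50 --seed 1 --out runs/demo

# reduce the long results table to Type-I / power / MAE summary tables
grmcompare summarize --results runs/demo/results.csv --out runs/demo

# fit and render the regression-tree summary of a table
grmcompare tree --table runs/demo/summary_power.csv --out runs/demo/tree.json
```

A YAML config (`--config`) with condition fields mapped to level lists
can replace or supplement `--cells`.

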