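# costbo

Cost-aware batch Bayesian optimization for discrete reaction design spaces.

Standard batch BO proposes the experiments with the highest expected
improvement regardless of what they cost. `costbo` penalizes each
candidate's acquisition value by the *current* price of the reagents it
needs: reagents already in the inventory are free, a reagent shared by
several members of a batch is charged once, and every purchase is recorded
in a ledger so costs update dynamically as the campaign proceeds. The
trade-off is controlled by a single weight `lambda` — at `lambda = 0` the
method is exactly standard batch BO.

Core pieces:

- **`costbo.chem`** — binary substructure fingerprints (RDKit Morgan),
  role-blocked candidate encoding, and a Tanimoto x squared-exponential
  product kernel.
- **`costbo.surrogate`** — exact GP regression (standardized yields,
  marginal-likelihood hyperparameter fitting, seeded joint posterior
  sampling).
- **`costbo.acquisition`** — per-candidate Monte-Carlo noisy expected
  improvement, the inventory-conditional cost `c(e)`, the scaling
  `S = lambda * max{alpha} / avg{p}`, and batch selection maximizing the
  cost-adjusted batch norm (greedy construction + swap refinement over a
  shortlist; exact on small pools).
- **`costbo.ledger`** — owned-compound set and purchase records; charges
  each compound exactly once; JSONL serialization.
- **`costbo.campaign`** — campaign loop (fit → score → select → commit →
  observe) for the `cibo`, `bo`, and `random` policies, ensembles over
  repeated seeds, spend-at-threshold reporting.
- **`costbo.data`** — design-space CSV I/O and a seeded synthetic benchmark
  generator (factorial reagent/condition grids, logistic yield surface,
  log-normal prices with a price–quality correlation knob).

## CLI

```sh
# generate a synthetic 1728-candidate benchmark
costbo generate --n-ligands 12 --seed 0 --out space.csv

# one cost-aware campaign (batch size 5, 20 iterations)
costbo run --data space.csv --policy cibo --lambda 1.0 \
    --batch-size 5 --iterations 20 --seed 7 --out out/

# compare bo / cibo / random ensembles at a 70% yield threshold
costbo compare --data space.csv --runs 5 --threshold 70 --out cmp/
```

`run` writes `trace.csv` (per-iteration best yield, cumulative spend, batch
composition, purchases) and `summary.json`; `compare` writes `report.csv`
with per-policy spend, compounds acquired, and savings relative to plain
BO. Initialization is `--init cheapest` (all candidates of the cheapest
ligand), `--init named:<id>`, or `--init indices:<i,j,...>`.

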