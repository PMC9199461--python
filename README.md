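# phenosink

Analysis pipeline for a carbon source–sink manipulation experiment on
deciduous saplings: does removing part of a tree's carbon **sources**
(leaves) or **sinks** (buds) shift the timing of autumn leaf senescence and
change late-season photosynthesis?

The package provides, end to end:

1. **Synthetic experiment generator** — a known-truth simulator of the full
   randomized-block experiment: 81 potted birch saplings in 8 treatments
   (25/50/75 % leaf removal, 25/50/75 % bud removal, a combined 50/50 arm,
   and an 11-tree control), arranged in 10 spatial blocks and 5 leaf-out
   groups, observed over one season through leaf/bud counts (13 campaigns),
   per-tree average SPAD chlorophyll (13 campaigns), and leaf-level net
   photosynthesis (6 gas-exchange campaigns).
2. **Quality control** of gas-exchange records: interval-day assignment,
   leaf-area correction for leaves too small to fill the chamber,
   plausibility screening, and principled handling of non-positive fluxes.
3. **Metrics** — the inverted relative SPAD index (a per-tree senescence
   score in [0, 1]), the day of year of 50 % senescence by interpolated
   threshold crossing, and trapezoidal totals of autumn photosynthesis at
   the leaf and whole-tree level.
4. **Inference** — linear mixed-effects models (REML) with the removal
   percentages as continuous covariates and random block intercepts,
   Type II Wald chi-square tests, interaction pruning, marginal/conditional
   R², and model-based (parametric) bootstrap confidence intervals.
5. **CLI & reporting** — a `phenosink` command with verbs
   `simulate`, `qc`, `metrics`, `fit`, `run`, `recover`, writing plain CSV
   plus a checksummed manifest for every run.

Because the generator injects configurable true effects, every stage of the
pipeline is validated by **parameter recovery**: simulate many replicate
experiments, run the full analysis, and check that the fitted effects match
the injected truth. See `docs/methods.md` for the model and all defaults.

## Worked example

Simulate one full experiment, clean it, derive per-tree metrics, and fit the
senescence endpoint model (seed 0 throughout — every number below is
reproducible verbatim):

```python
from phenosink import (
    SimulationConfig, generate_design, simulate_experiment, compute_tree_metrics,
)
from phenosink.qc import MeasurementSchedule, run_qc
from phenosink.inference import (
    endpoint_spec, prune_interactions, fit_lmm, effect_tests, bootstrap_ci,
)

cfg = SimulationConfig(seed=0)
design = generate_design(0)
tables = simulate_experiment(design, cfg)

clean, log = run_qc(tables["photosynthesis"], MeasurementSchedule.from_config(cfg))
print(log["action"].value_counts().to_dict())
# {'kept': 463, 'dropped': 13, 'zeroed': 10}

met = compute_tree_metrics(clean, tables["counts"], tables["spad"],
                           cfg.leaf_removal_1_doy)
frame = met.merge(tables["trees"], on="tree_id").rename(
    columns={"leaf_removal_pct": "leaf_pct", "bud_removal_pct": "bud_pct"})
print(frame[["tree_id", "treatment", "doy_50pct", "total_autumn_photo"]]
      .head(3).round(2).to_string(index=False))
# tree_id treatment  doy_50pct  total_autumn_photo
#     T01   control     295.99              412.13
#     T02   control     290.40              471.65
#     T03   control     286.11              457.35

data = frame[frame["doy_50pct_defined"]]
spec, pruned = prune_interactions(endpoint_spec("doy_50pct"), data)
print(pruned)            # [('leaf_pct:bud_pct', 0.362)]  -- interaction dropped
fit = fit_lmm(spec, data)
print(fit.coefficient_table().round(4))
#            estimate      se       p
# Intercept  293.6550  2.6429  0.0000
# leaf_pct     0.0527  0.0451  0.2423
# bud_pct      0.0312  0.0451  0.4893

ci = bootstrap_ci(fit, n_sim=1000, seed=0)
print(ci[ci["bud_pct"] == 0].round(2).to_string(index=False))
#  bud_pct  leaf_pct    fit  se_boot  lower95  upper95
#        0         0 293.65     2.64   288.47   298.84
#        0        25 294.97     2.20   290.65   299.29
#        0        50 296.29     2.28   291.82   300.76
#        0        75 297.61     2.83   292.06   303.16
```

This single replicate estimates a senescence delay of 0.053 days per percent
of leaves removed (SE 0.045) — one experiment of this size is noisy, which is
exactly why the injected truth and the recovery study below exist. The same
run gives a +10.6 % difference in total autumn photosynthesis between 75 %
leaf removal and control.

The same pipeline as one command:

```bash
phenosink run --out results/run0 --seed 0 --boot 1000
```

writes `trees.csv`, the three observation tables, `photosynthesis_clean.csv`,
`qc_log.csv`, `metrics.csv`, `coefficients.csv`, `tests.csv`,
`predictions.csv`, `spad_by_treatment.csv`, and a `manifest.json` with a
SHA-256 checksum of every file. Re-running with the same seed reproduces
every file byte for byte.

## Layout

```
src/phenosink/
  design.py     treatments, blocks, leaf-out groups, design randomization
  config.py     SimulationConfig: calendar, true effects, noise model
  simulate.py   observation-table generator + CSV round trip
  qc.py         gas-exchange cleaning chain
  metrics.py    senescence index, 50 % crossing, AUC totals
  inference.py  mixed models, tests, R², bootstrap, recovery study
  pipeline.py   run orchestration, summaries, manifest
  cli.py        click-based command line
docs/methods.md model, parameter defaults and rationale, limitations
scripts/acceptance.py  recompute all headline numbers from scratch
```
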