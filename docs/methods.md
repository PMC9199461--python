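# Methods

This note documents the data-generating model behind the synthetic
experiment, the default parameter values and why they were chosen, the
numerical conventions used throughout the pipeline, and the known
limitations of both the generator and the estimators.

## 1. Experimental design

81 potted saplings receive one of eight treatments: removal of 25, 50 or
75 % of leaves (carbon sources), 25, 50 or 75 % of buds (carbon sinks), a
combined 50 % leaf + 50 % bud arm, or control. Ten trees per treatment,
eleven controls. Trees sit in ten spatial blocks — one tree per treatment
per block, with the eleventh control doubling up in a random block — and
carry one of five leaf-out groups (earlier-flushing trees carry more
leaves), balanced within treatment. `generate_design(seed)` randomizes
block and group assignments reproducibly.

Season calendar (2020, days of year): first leaf removal DOY 163 (Jun 11),
bud removal DOY 216 (Aug 3), second leaf removal DOY 225 (Aug 12); 13
count/SPAD campaigns starting DOY 227–334; 6 gas-exchange campaigns
starting DOY 240–326. The senescence modeling window starts September 30
(DOY 274), which retains the last 9 of the 13 count/SPAD campaigns.

## 2. Data-generating model

### Senescence

Each tree *t* has a latent senescence midpoint

```
m_t = mu + delta_L * leaf_pct_t + delta_B * bud_pct_t + b_block(t) + b_tree(t)
```

with Gaussian block and tree intercepts. Average SPAD follows a falling
logistic `plateau / (1 + exp((d - m_t) / s))`; the leaf count declines
along the same logistic lagged by a fixed number of days. Because every
curve of a tree shifts rigidly with `m_t`, an injected per-percent delay
`delta_L` propagates one-to-one into the day of 50 % senescence — the
derived metric recovers exactly the injected effect in the noise-free
limit, which is what makes the generator a usable truth standard.

### Leaf and bud counts

Counts start from a leaf-out-group-dependent baseline, are cut by the
treatment percentage at each removal event (post-removal count =
`round((1 - pct/100) * pre)`, banker's rounding), regrow between leaf
removals at a fixed fraction of the removed count per day (Poisson when
noise is on, capped at 1.5× the initial count), and decline with the
lagged senescence logistic in autumn. Buds are removed once, regrow
slowly, and do not senesce. Observed scheduled counts carry proportional
census error: `observed = max(0, round(expected * (1 + eps)))`,
`eps ~ N(0, cv)`.

### Photosynthesis

Leaf-level net photosynthesis declines along a seasonal logistic. Its
amplitude scales linearly along the leaf-removal gradient so that the
noise-free AUC of a 75 %-removal tree exceeds the control's by exactly the
configured percentage (a remaining-leaves-work-harder compensation).
Multiplicative tree and block effects and additive measurement noise are
applied on top. The recorded flux is the chamber-basis value — the true
leaf flux times the fraction of the chamber the leaf covers — so QC's
leaf-area correction is exercised by construction, as are a small rate of
records with an implausible negative stomatal conductance and trees that
go leafless before the last campaign.

## 3. Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| `true_senescence_delay_per_pct` | 4.31/75 ≈ 0.0575 d/% | Study condition: a 4.31-day delay of 50 % senescence at 75 % leaf removal (0.06 d/% at two-decimal precision). |
| `true_bud_delay_per_pct` | 0 | Study condition: bud removal is a null effect; settable for power analyses. |
| `true_photo_effect_pct` | 14 % | Study condition: increase in total leaf-level autumn photosynthesis at 75 % removal vs control. |
| `spad_midpoint_doy` | 295 | Baseline 50 %-senescence date (late Oct); keeps all crossings, including delayed ones, inside the DOY 227–334 observation span. |
| `spad_plateau`, `spad_steepness` | 40, 6 d | Typical SPAD plateau for birch; 6-day time constant gives a decline spread over ~4 weeks, resolvable by weekly campaigns. |
| `count_decline_lag`, `count_decline_steepness` | 12 d, 5 d | Leaf drop trails chlorophyll loss by about two weeks and is slightly sharper. |
| `tree_midpoint_sd`, `block_midpoint_sd` | 10 d, 4 d | Calibrated so a single 81-tree experiment yields a slope standard error ≈ 0.04–0.05 d/%, matching the reported uncertainty of the leaf-removal coefficient; block SD is set well below tree SD, as usual for container experiments on a single pad. |
| `spad_noise_sd` | 1.2 | SE of a per-tree mean of ~10–15 individual SPAD readings (single-leaf scatter ±2–3 units). |
| `count_noise_cv` | 0.03 | Whole-plant counts are censuses; miscount error scales with the count (a 3 % CV is ±1 leaf on a 40-leaf tree). An additive error model was rejected: a fixed ±2-leaf error is a ~17 % relative error on a 75 %-defoliated tree, inflates its seasonal count×SPAD maximum, and systematically attenuates the recovered slope. |
| `photo_amplitude` | 9 µmol m⁻² s⁻¹ | Early-autumn birch leaf-level net photosynthesis. |
| `photo_midpoint_doy`, `photo_steepness` | 288, 12 d | Seasonal decline reaching ~half by mid-October. |
| `photo_tree_sd`, `photo_block_sd` | 0.15, 0.05 (CV) | Between-tree spread of gas-exchange amplitudes; gives realistic scatter of group-mean AUC ratios. |
| `photo_noise_sd` | 0.4 | Instrument/within-leaf repeatability. |
| `leaf0_mean/sd`, `bud0_mean/sd` | 40 ± 8, 30 ± 6 | Sapling-scale organ counts. |
| `regrowth_gain`, `bud_regrowth_gain` | 0.02, 0.015 /d | Partial compensatory regrowth between events: a 75 %-removal tree recovers a noticeable fraction of its removed leaves in the 62 days between leaf removals, motivating the second removal. |
| `qc_artifact_rate`, `small_leaf_rate` | 0.03, 0.15 | Realistic rates of implausible-covariate records and of leaves too small to fill the chamber. |
| `leafout_count_effect` | 0.04 per group step | Earlier-flushing trees carry more leaves; leaf-out has deliberately no effect on phenology, so it is pure, balanced nuisance variation. |

The injected effect sizes are the **study conditions** of the experiment
the generator models; they were fixed before any recovery experiment and
are not tuned to recovery outcomes. Note one deliberate choice: the
per-percent delay and the 75 %-delay are the *same* coefficient expressed
at two precisions (0.06 × 75 = 4.50 ≠ 4.31), so the generator uses the
higher-precision 4.31-day form as its single internal truth.

## 4. Analysis conventions and numerical choices

- **Inverted relative SPAD index**: `|LC_d·SPAD_d / max_i(LC_i·SPAD_i) − 1|`
  per tree, with the maximum over all 13 dates taken *before* any
  windowing, so the index is anchored at the true seasonal peak and lies
  in [0, 1].
- **Day of 50 % senescence**: the *last* adjacent pair with
  `v_i ≤ 0.5 ≤ v_{i+1}` and `v_i < v_{i+1}`, linearly interpolated. The
  crossing is searched on the full 13-date series: restricting the search
  to the post-cutoff window would censor early-crossing trees
  asymmetrically across treatments and attenuate the treatment contrast
  (confirmed in simulation). Trees that never reach 0.5 are flagged
  undefined, not errors, and excluded from the endpoint model.
- **AUC time base**: trapezoidal rule with x in days; totals carry units of
  µmol m⁻² s⁻¹·day and no 86 400 s/day conversion is applied. All reported
  effects are ratios or percent differences, which this convention leaves
  unchanged.
- **Closest-count scaling** for tree-level carbon gain: each flux is scaled
  by the closest-in-time leaf count over the pre-treatment count;
  equidistant ties resolve to the earlier census.
- **Rounding**: all count arithmetic uses round-half-to-even (NumPy
  default), documented so event censuses are exactly reproducible.
- **QC order**: interval-day assignment → leaf-area correction
  (`a_net / covered_fraction`) → plausibility screen (default rule:
  stomatal conductance ≥ 0) → non-positive resolution (negative fluxes are
  kept as zero only when zero is biologically meaningful: final interval,
  or leafless by the next interval; otherwise dropped; exact zeros kept) →
  injected season-end zeros for leafless trees with no surviving final
  record. The chain is idempotent, and the log accounts for every record.
- **Mixed models**: statsmodels `MixedLM`, REML, removal percentages as
  continuous covariates, random block intercept (plus a plant intercept in
  the longitudinal specification). Optimizer order (powell, lbfgs, cg,
  nm): on the 81-row endpoint model Powell converged in 100/100 trials at
  ~30 ms where the default reported spurious non-convergence and L-BFGS
  raised singular-matrix errors. Non-convergence is flagged on the result,
  never hidden. Exactly collinear or noise-free data short-circuit to an
  exact least-squares solution with zero variance components (the REML
  problem is degenerate there).
- **Type II Wald chi-square tests** honoring marginality: a main effect is
  tested in a refit without the interactions containing it; continuous
  covariates carry 1 df.
- **Interaction pruning**: highest-order interactions first; the least
  significant one at α = 0.05 is dropped and the model refit, repeating;
  main effects are never pruned.
- **R²**: Nakagawa–Schielzeth marginal (fixed-effect variance over total)
  and conditional (fixed + random over total); negative variance estimates
  are clamped to zero with a warning.
- **Bootstrap**: model-based (parametric) — simulate responses from the
  fitted model, refit, collect per-condition predictions; 95 % limits are
  the point prediction ± 1.96 × SD of the bootstrap predictions, computed
  on the model scale and back-transformed. Failed refits are dropped and
  counted; more than 10 % failures raises. A zero-total-variance model
  short-circuits to width-zero intervals (every simulated response equals
  the fitted mean, so all replicates coincide by construction).
- **Seeding**: all generator randomness derives from
  `default_rng([seed, stream, unit])` — independent purpose-keyed streams
  per tree/block — so tables are bit-identical across runs and each tree
  can be simulated in isolation. The recovery study derives child seeds
  from a `SeedSequence`, keeping them below 2³¹.

## 5. Generator realism limits

- Senescence curves shift rigidly with treatment; real treatments could
  also change the *shape* (steepness) of the decline.
- SPAD noise is homoscedastic in absolute units, so the *relative* error
  grows late in the season; real SPAD error is closer to constant-CV.
- Leaf regrowth is linear-in-time with a hard cap; no second-flush
  phenology.
- The photosynthesis compensation is imposed directly on the amplitude
  rather than emerging from a carbon-balance model; the bud arm has no
  photosynthesis response at all.
- Weather, daylength and temperature — the physical drivers of autumn
  senescence — are not modeled; everything is calendar-driven.
- Gas-exchange artifacts are independent coin flips, not operator- or
  day-clustered as real artifacts tend to be.

## 6. Known estimator limitations

- **Small positive crossing bias**: with the default noise, the 200-replicate
  mean recovered slope sits ≈ +0.004 d/% above truth (≈ 1.4 Monte-Carlo
  SEs; reproducible across master seeds). The last-rising-crossing rule
  occasionally selects a later, noise-induced re-crossing of the 0.5
  threshold, a small positive shift amplified slightly by the coarser
  late-season schedule (the final count/SPAD gap is 11 days vs 7 mid-season).
  The rule is the study's published estimator, so the bias is documented
  rather than "fixed".
- **Interpolation bias in the noise-free limit**: linear interpolation
  across a convex logistic overstates the implied 75 %-delay by ~0.2 days
  (4.5 vs 4.3 recovered noise-free); sub-interval accuracy is inherently
  limited by the weekly schedule.
- A single 81-tree experiment has a slope SE ≈ 0.04–0.05 d/%, so individual
  replicates frequently produce non-significant or even negative slope
  estimates; only the replicate ensemble pins down the effect.
- The bootstrap treats estimated variance components as known, which
  slightly understates interval width in small samples (the usual
  parametric-bootstrap caveat).
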