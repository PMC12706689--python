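# Methods

This note records the statistical model, the conventions the package
fixes, the choices that were genuinely open, and what the synthetic-data
benchmarks do and do not demonstrate.

## Model and procedure

Each subject-condition block of cleaned EEG is an `epochs × channels ×
samples` array (defaults: 4-s epochs at 500 Hz, 32-channel 10–20 montage).
Epochs are treated as independent realizations of a stationary vector
autoregression of order p; the analysis chain is

stationarity → (order selection) → epoch-wise conditional Granger
causality → winsorized subject summaries → group consistency + FDR →
thresholded networks, region tables and condition differences.

### Stationarity enforcement

Granger inference on unit-root series produces spurious regressions, so
every channel of every epoch is tested with the augmented Dickey–Fuller
test (null: unit root) before modeling.

* Regression term: constant (`"constant"`). Epochs are near-zero-mean
  after preprocessing but can retain drift offsets; a trend term is
  available, as is the no-constant variant.
* Augmentation lags: chosen by AIC up to the Schwert bound
  ⌊12·(T/100)^0.25⌋. A fixed lag (including 0, the plain Dickey–Fuller
  regression) is available since the original analysis's choice between
  the plain and augmented variants is not fixed by the method description.
* Policy: difference, retest, difference again, stop — at most two
  differences, preserving interpretability. Channels still non-stationary
  after two differences are flagged in the report and retained; no
  exclusion rule is imposed.
* Alignment: differencing of order d shortens a channel by d samples.
  After the per-channel decisions all epochs are truncated from the front
  to the common length `samples − max(applied order)`, keeping the array
  rectangular; already-stationary channels are truncated, never
  re-differenced, so their dynamics are untouched. Decisions are made per
  epoch and channel, not harmonized across a subject's epochs.

The ADF regression itself is delegated to statsmodels (MacKinnon response
surfaces); an independently coded least-squares oracle pins the fixed-lag
t-ratio in the tests.

### VAR estimation and order selection

Each channel's equation is estimated by OLS on p lags of all channels plus
an intercept, with epochs stacked so that the first p samples of each
epoch serve only as regressors (no cross-epoch lag contamination).
Criteria use the multivariate form `ln det(Σ̂) + penalty · k / T_eff` with
penalties 2 (AIC), ln T_eff (BIC), 2 ln ln T_eff (HQC); candidate orders
1..max are scored on a common estimation sample (presample = max order).
The default configuration imposes order 10 (`criterion="fixed"`, a 20 ms
history window at 500 Hz) rather than searching, since a maxlag-10
analysis is the reference; BIC selection is the default in the planted-
edge benchmark, where it recovers the true order.

### Conditional Granger causality

For each ordered pair, F = [(RSS_reduced − RSS_full)/p] /
[RSS_full/(T_eff − k_full)] with p-values from F(p, T_eff − k_full) — the
finite-sample F reference, not the asymptotic chi-square. Conditioning
defaults to `"full"` (all remaining channels in both models), which
suppresses indirect paths; `"bivariate"` is retained as a comparison mode
because the original conditioning set is not recoverable from the method
description. Estimation defaults to `"per_epoch"` (each epoch an
independent fit), matching the epoch-wise framework; `"pooled"` stacks all
epochs into one regression. The full-model fit is shared across targets:
one full regression per target and one reduced regression per source, so
a 32-channel epoch costs 2C multi-response least-squares solves rather
than C(C−1) pairs × 2.

### Subject summaries

Within one subject-condition, the pool of all defined F entries over all
epochs is winsorized at [Q1 − 1.5·IQR, Q3 + 1.5·IQR] (quantiles by linear
interpolation of order statistics — fixed for reproducibility and tested),
capping outliers rather than removing them, then averaged per pair.
Epoch p-values combine by Fisher's method (−2Σln p ~ χ²(2k)); a
majority-vote rule (> 50% of epochs with p < 0.05) is available as
`combine="proportion"`.

### Group inference

Per pair: mean and SD of subject F (SD with ddof = 1); consistency = the
fraction of subjects significant, where each subject's per-pair decisions
apply BH-FDR across that subject's defined pairs at α = 0.05
(`fdr_scope="subject"`, the default; `"none"` gives raw p < 0.05, since
the description supports both readings). Robustness requires consistency
**strictly** greater than 0.95: with 40 subjects, 39 significant (0.975)
qualifies and 38 (0.95 exactly) does not. A separate `fdr_rejected` field
applies BH across pairs to Fisher-combined subject p-values; effect sizes
are z-scored across defined pairs. The visualization threshold is
mean + 1 SD of the group-mean F over defined pairs, always recomputed.

The SD population is a known ambiguity: a published summary can take the
SD over all pairs or over significant pairs only, and the two differ.
This package computes it over all defined pairs and exposes the matrices
so either can be derived.

### Networks, regions, differences

`extract_network` keeps edges with group-mean F strictly above threshold.
Region aggregation uses a shipped, user-overridable table grouping the 32
sites into frontal (Fp1…FT8, 12 sites), central (C3, Cz, C4), left
temporal (T7, TP7, TP9), right temporal (T8, TP8, TP10), parietal
(CP3…P8, 8 sites) and occipital (O1, Oz, O2); 2-D positions come from the
standard 10–20 layout.

The difference map is fixed to **color − lexical** (positive =
color-dominant). Published prose on this sign is internally inconsistent,
so the convention is documented at the interface rather than claimed as a
reproduction. "C"/"L" markers flag pairs robust in exactly one condition.
The "*" marker is an interpretation choice: the method description does
not state how difference-map significance was computed, so this package
uses a paired per-subject Wilcoxon signed-rank on the pair's F values,
BH-corrected across pairs (requiring the same subjects in both
conditions, the within-subject design).

## Behavioral battery

Implemented from the defining formulas, with scipy as an independent
cross-check in the tests:

* **Chi-square independence** — Pearson statistic, no Yates correction
  (the continuity-corrected statistic would not reproduce the reference
  value on the published 2 × 3 table); zero margins error, expected counts
  below 5 warn.
* **Mann–Whitney U** — U reported for the first sample from midrank sums;
  normal approximation with tie-corrected variance and 0.5 continuity
  correction; exact enumeration of all assignments when n₁ + n₂ ≤ 12.
* **Kruskal–Wallis** — tie-corrected H; all-identical data returns H = 0
  by convention (the correction degenerates 0/0).
* **Dunn–Bonferroni** — pairwise z on mean ranks with the pooled
  tie-corrected variance N(N+1)/12 − Σ(t³−t)/(12(N−1)); p × number of
  comparisons, capped at 1.
* **Spearman ρ** — Pearson correlation of midranks, two-tailed t
  approximation. **Kendall τ-b** — pair counts with standard tie terms
  and the full tie-corrected normal variance.

Mixed-effects models (participant and odor random intercepts) and Tukey
HSD post hocs are deliberately out of scope; `run_battery` notes where
they would slot in.

## Synthetic data

The generator defines the study conditions the pipeline is validated
under.

* **VAR epochs** — a `VarSpec` is accepted only if the companion-matrix
  spectral radius is < 1 and the innovation covariance is symmetric
  positive definite. Each epoch starts from a fresh burn-in of
  max(10p, 50) discarded samples, so epochs are independent draws from
  the stationary distribution. `inject_unit_root` integrates chosen
  channels once or twice within each epoch to exercise the differencing
  policy.
* **Benchmark cohort** — `planted_spec()` is a 6-channel VAR(2) with
  self-dynamics 0.3/0.15 and five lag-1 edges at coupling 0.4
  (0→1, 0→2, 1→3, 2→4, 4→5 — containing chains, so conditional GC must
  suppress indirect paths). Subjects receive N(0, 0.02) coefficient
  jitter (redrawn smaller if unstable). Benchmark runs use 40 subjects ×
  10 epochs × 1.5 s; detection power at coupling 0.4 is saturated well
  below the full 36 × 4-s design, and a full-scale run gives the same
  exact recovery.
* **Trial tables** — the full counterbalanced design: even n splits into
  two groups with the two six-odor sets crossed over cue types, 6
  repetitions each, so n = 40 yields 2,880 rows. Response categories
  follow the observed marginal rates (no answer ≈ 0.306/0.305, correct
  0.179/0.530 for color/lexical) via a two-stage draw (answer, then
  correct-given-answer through a logistic link); familiarity and liking
  enter the accuracy log-odds (+0.25, +0.10 per rating point) and log-RT
  (−0.08, −0.03, log-normal with μ = 0.45, σ = 0.9, matching the ~2.3 s
  mean and heavy tail of observed response times). No-answer trials carry
  missing RT, since the RT measure is keyed to a response-initiating
  keypress. Ratings are drawn per trial; per-odor random intercepts are
  available via `odor_sd` but default to 0 because the rank-based battery
  ignores odor-level structure. Per-odor accuracy variances are not
  published; these defaults are free choices of the generator.

### What the benchmarks show — and do not

Passing the planted-edge benchmark shows the chain
stationarity → GC → winsorizing → consistency → FDR recovers a known
directed graph with zero false robust edges under Gaussian VAR
assumptions with mild between-subject variation. It does not show
robustness to volume conduction, shared reference artifacts, non-Gaussian
or non-stationary-within-epoch dynamics, or channel-count/epoch-count
regimes far from those simulated; channels here are abstract VAR nodes,
not forward-modeled scalp potentials.

## Numerical conventions

* Quantiles: linear interpolation of order statistics everywhere.
* SDs: ddof = 1 (sample SD) at subject and group level.
* p-values clipped at 1e-300 before logs in Fisher combination.
* F statistics are floored at 0 (tiny negative round-off from the nested
  solves is truncated).
* Strict inequalities at the robustness cut and network threshold; ties
  at the boundary do not pass.
* All randomness flows through `numpy.random.default_rng` /
  `SeedSequence`; identical seeds give bit-identical arrays and tables.
* Degenerate inputs: constant series, empty samples, zero margins,
  rank-deficient designs, unknown channels and out-of-range probabilities
  raise with context rather than propagating NaNs.

## Known limitations

* Time-domain GC only: no spectral (frequency-resolved), state-space or
  Wilson-factorization variants.
* Electrode space only; no source localization or 3-D head rendering.
* The group difference "*" marker is one defensible definition among
  several (see above).
* With `conditioning="full"` and order 10 on 32 channels, each equation
  has 321 parameters; per-epoch fits need T_eff comfortably above that
  (the 2,000-sample epochs of the reference design suffice, shorter
  epochs may require pooling).
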