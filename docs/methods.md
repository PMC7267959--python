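# Methods

This note documents the models, numerical choices and limitations of `wnet`,
stage by stage. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohorts

The generator is deliberately the *simplest* signal model whose phase
structure a weighted phase-lag estimator provably detects, so that the
pipeline has analytic limits to test against — not a biophysical simulator.

- **Layout.** Electrodes lie on a Fibonacci spiral over the upper cap of an
  87.5 mm sphere (so all inter-electrode distances are ≤ 175 mm, inside the
  227 mm ceiling of the distance bins), with a small seeded angular jitter.
  Scalp regions are assigned by a coordinate quadrant rule (anterior →
  frontal, posterior → posterior, midline → central, temporal band →
  lateral), since only a regional partition — not true montage geometry — is
  needed downstream.
- **Signals.** Per band, every channel carries an independent sinusoid at an
  epoch-jittered in-band frequency with a random phase, plus white noise
  (default sd 0.2 relative to unit oscillation amplitude). A planted edge
  (i, j) with strength c and lag φ replaces channel j's band component by
  `c·carrier_i(t−φ) + (1−c)·own oscillator`. Limits: c = 1, zero noise gives
  WPLI exactly 1 at the planted lag; c = 0 leaves the pair with no
  systematic phase relation. Defaults: 2 s epochs at fs = 256 Hz
  (configurable; chosen so the slowest 3-cycle window fits comfortably and
  all band edges sit far below Nyquist).
- **Groups.** A group attenuates planted coupling multiplicatively per band;
  each subject additionally receives a ±15% multiplicative jitter, which is
  the between-subject variance that makes rank statistics and planted
  clinical correlations meaningful. Clinical scores are Gaussian per group;
  a planted rank correlation ρ against the subject's latent mean coupling is
  produced by Gaussian mixing (`ρ·z_trait + sqrt(1−ρ²)·noise`), which
  approaches but does not guarantee the target (tolerance about ±0.1).
- **What it does not emulate.** Volume conduction, 1/f background spectra,
  artifacts, non-stationarity, or realistic effect sizes — the real cohort's
  per-edge effects are unpublished, so planted effects are free parameters.
  Passing recovery tests therefore demonstrates the *pipeline's* correctness
  and sensitivity under known ground truth, not expected performance on
  clinical EEG.

## Connectivity

The time-frequency transform is a windowed Fourier transform on a 0.5 Hz
grid: at frequency f the window lasts cycles(f)/f seconds, with cycles
ramping linearly from 3 at the band's low edge to 10 at the high edge
(clipped to the epoch), Hann-tapered, sliding at 50% overlap. Coefficients
are normalised by the taper sum so power is comparable across
frequency-dependent window lengths. WPLI pools the expectation jointly over
epochs, windows and in-band bins (`pooling="joint"`); a per-epoch-then-mean
variant is exposed for sensitivity analysis since the pooling order is a
genuinely open choice. The taper is likewise a choice the underlying method
description leaves open; Hann is the default of the major EEG toolboxes.
Pairs whose imaginary cross-spectrum is identically zero (e.g. exactly
zero-lag signals) get WPLI 0 — "lack of connectivity", not NaN.

Spectral leakage makes adjacent bands (α upper edge 13.5 Hz, β lower edge
14 Hz) partially sensitive to each other's coherent sources with these short
windows; the band-specificity test accounts for this.

## Graphs and metrics

- Proportional thresholding keeps k = round(PT/100 · n(n−1)/2) strongest
  upper-triangle edges (round half up; the reference toolbox truncates —
  the difference is at most one edge). Ties at the cut go to the lowest
  (row, column) index, making the sweep fully deterministic and nested.
  The default grid 3–60% in 1% steps yields 58 levels. (Descriptions of
  this design elsewhere sometimes count "60 levels"; the grid above is the
  one implemented, and the discrepancy is deliberate, not re-interpreted.)
- Weighted clustering uses the Onnela geometric-mean triangle formula on
  max-rescaled weights; weighted path length uses 1/w edge lengths
  (connectivity as proximity). Both reduce *exactly* to their binary
  counterparts when all surviving weights are 1 — the "bridge invariant"
  the suite checks across the full sweep.
- Disconnected node pairs are excluded from the path-length average (with a
  logged count) rather than entering as infinities; a graph with no finite
  path at all raises a degenerate-input error. This matters only at very
  low PT%.
- Modularity is Louvain with 10 seeded restarts (best Q kept), resolution 1.
- Surrogate normalisation uses degree-preserving double-edge-swap rewiring
  (10 swaps per edge); weighted graphs additionally shuffle surviving
  weights over the rewired topology. Default 50 surrogates. The rewiring
  and weight-shuffle random streams are independent so binary and weighted
  surrogates share topologies — required for the bridge invariant. If
  rewiring fails on a degenerate graph the code warns and falls back to
  weight-shuffle-only surrogates.
- The regional partition treats "temporal" and "lateral" as the same region
  set.

## Density dependence

Spearman ρ between pooled metric values and PT levels, with a null of
n_perm = 5,000 value-against-level permutations; significance is a two-sided
2.5%-per-tail criterion on that empirical null. Pooling across all groups
and bands is the default headline analysis; per-group curves are exposed.

The power-law fit `value = scale·t^exponent + offset` (t = PT/100) uses
Levenberg–Marquardt from five exponent starts {0.05, 0.25, 0.5, 1, 2} with
the conditionally linear coefficients initialised by least squares; 95% CIs
come from the linearised covariance with a t-quantile. Whether curves are
fitted per subject or on the group mean is an open design point; the
pipeline fits the group-mean curve and exposes per-subject fitting.

The derivative-ratio condition is solved analytically: the ratio of the
weighted to the binary derivative is (mn/fg)·t^(n−g), so the condition
"< 1" switches at t\* = (fg/mn)^(1/(n−g)), with direction given by
sign(n−g); empty and full intervals are returned explicitly. Preconditions:
positive scales, nonzero exponents of equal sign (otherwise the two
derivatives have opposite signs and the magnitude comparison is ill-posed —
the L fits in the demo, where binary L falls but the fitted weighted scale
is negative, hit exactly this and the report says so rather than inventing
an interval).

## Group statistics

- Kruskal–Wallis with average-rank tie correction; an all-tied input
  returns H = 0, p = 1 rather than NaN.
- Mann–Whitney U: exact p for tie-free groups of ≤ 8, otherwise the normal
  approximation with tie and continuity correction. Holm–Bonferroni over
  the six pairwise comparisons (statsmodels step-down).
- Mack–Skillings: within-block average ranks, centred group rank sums
  scaled by 1/(N_block+1), quadratic form against the exact
  finite-population within-block covariance (pseudo-inverse, df = k−1).
  This handles ties and unequal replication exactly and reduces to
  Friedman at one observation per cell; it is validated against a
  within-block permutation oracle.
- NBS: per-edge one-way F (or pooled one-tailed t for two groups),
  component-forming thresholds default 8 (F) and 3.8 (t), component extent
  (edge count) as the cluster statistic, FWER p = (1 + #{null max ≥ obs}) /
  (n_perm + 1) over label permutations; the Bonferroni family for post hoc
  scenarios is 12 comparisons. A threshold letting through > 50% of edges
  triggers a warning.
- Regional gate: mixed-design ANOVA (region within, group between) via
  pingouin with sphericity assumed; Greenhouse–Geisser correction is an
  option. Per-region rank tests run only when the interaction is
  significant.
- Clinical correlations are deliberately uncorrected and flagged as such;
  fewer than 5 pairs flags the estimate unstable.

## Classification

Random forest (500 trees by default), stratified 6-fold × 10 repeats.
Class imbalance is handled by random undersampling of the majority class
inside each training fold (class weighting is the exposed alternative);
the exact imbalance routine used in comparable studies is typically
unreported, so the simplest member of that family was chosen. Reported:
per-fold accuracy, F1, PPV, NPV, sensitivity, specificity and AUROC as
mean ± sd; a pooled out-of-fold ROC curve; its Youden-optimal point
(argmax TPR − FPR, ties toward specificity); impurity-based importances
averaged over all fits.

## Problem sizes and reproducibility

All randomness flows through one master seed via a deterministic
key-folding derivation (`wnet._utils.derive_seed`), so cohorts, surrogates,
permutation nulls and forests are bit-reproducible. The test suite and the
demo configuration use reduced problem sizes — 8–32 channels, 4–10 epochs,
200–500 permutations, 100-tree forests — chosen so the full suite runs in
about two minutes while every statistical property under test (recovery,
calibration, invariance) is still well resolved; the API defaults remain at
the full-scale values (5,000 permutations, 50 surrogates, 500 trees).

## Known limitations

- The sinusoid-plus-noise generator cannot probe robustness to volume
  conduction, even though WPLI's motivation is exactly that robustness.
- Coupling chains dilute: a planted edge mixes the *latent* oscillator of
  its first endpoint, so paths of planted edges do not compose into strong
  WPLI paths; planted connected structures should be stars or disjoint
  pairs.
- Only the three-parameter power law is fitted; exponential/polynomial
  model comparison is out of scope (the linear baseline appears only as a
  test oracle).
- MST-based construction, absolute thresholding, betweenness/efficiency
  metrics and targeted-attack analyses are out of scope.
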