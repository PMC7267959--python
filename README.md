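# wnet — weighted EEG functional-network analysis

`wnet` is a tested re-implementation of a sensor-space EEG functional-network
pipeline for dementia research (healthy controls vs Alzheimer's disease vs
Lewy-body dementias). It estimates phase-based functional connectivity from
epoched multichannel recordings, builds proportionally thresholded graphs in
both *binary* and *weight-preserving* form, quantifies how strongly each graph
measure depends on the chosen network density, and runs the accompanying
group-difference, correlation and classification statistics. Because clinical
EEG datasets of this kind are rarely shareable, the package ships a synthetic
cohort generator with planted, band-specific connectivity effects so every
stage is testable end to end without any download.

## The model

**Connectivity.** For each channel pair, the weighted phase lag index

    WPLI = |E[I(X)]| / E[|I(X)|]

where *X* is the windowed-Fourier cross-spectrum, *I(X)* its imaginary part,
and the expectation runs over epochs, time windows and in-band frequency bins
(θ 4–7.5 Hz, α 8–13.5 Hz, β 14–20.5 Hz; 0.5 Hz grid; 3→10-cycle adaptive Hann
windows). WPLI ∈ [0, 1]; near-zero-lag (volume-conducted) coupling is
down-weighted by construction.

**Graphs.** Each WPLI matrix is normalised by its maximum and thresholded at
PT% ∈ {3, …, 60}, keeping the strongest round(PT/100 · n(n−1)/2) edges —
either binarised or with surviving weights preserved. Measures: degree /
strength K, clustering C (Onnela geometric-mean form when weighted),
characteristic path length L (1/w edge lengths when weighted), Louvain
modularity Q, and small-worldness σ = N-C/N-L from degree-preserving rewired
surrogates.

**Density dependence.** Metric-vs-PT% curves are tested with Spearman ρ
against a 5,000-permutation null, and fitted with a power law
C_b = f·t^g + h (binary) and C_w = m·t^n + q (weighted), t = PT/100. The
weighted measure is less density-dependent wherever the derivative ratio

    (m·n·t^(n−1)) / (f·g·t^(g−1)) < 1,   0 < t ≤ 1

which `derivative_ratio_condition` solves in closed form
(boundary t\* = (fg/mn)^(1/(n−g))).

**Statistics.** Kruskal–Wallis → Mann–Whitney U with Holm–Bonferroni;
Mack–Skillings rank test across threshold blocks; a network-based statistic
(NBS) with permutation FWER control over supra-threshold connected
components; edge-distance-range comparisons; a mixed-design region×group
ANOVA gate; uncorrected Spearman correlations with clinical scores; and a
random-forest classifier (stratified 6-fold × 10 repeats, undersampling,
Youden-optimal ROC point, impurity-based feature ranking).

## Worked example

Run the bundled demo cohort (4 groups × 8 subjects, 32 channels; the
dementia-like groups have attenuated α coupling, the DLB-like group an extra
β attenuation):

```python
from wnet import demo_config, run_all
run_all(demo_config(seed=1), "demo_run")
```

`demo_run/density_report.json` then contains (seed 1):

```
degree:       rho_binary = 1.000,  rho_weighted = 0.809
clustering:   rho_binary = 0.988,  rho_weighted = 0.757
path_length:  rho_binary = -0.969, rho_weighted = -0.265
clustering weighted-flatter interval: (0.026, 1]
```

Every binary measure is strongly correlated with the threshold level, while
its weight-preserving variant is markedly flatter — the package's central
methodological point: preserving weights protects graph measures from the
arbitrary choice of network density. For the clustering coefficient, the
closed-form slope comparison says the weighted curve is flatter on
essentially the whole density range (t > 0.026).

`demo_run/classification.json` shows the planted β effect dominating the
DLB-vs-AD classifier (top-ranked features `beta_degree`, `beta_path_length`;
AUROC 1.0 on this strongly separable synthetic cohort), and
`demo_run/stats/` holds the group tests, NBS components and clinical
correlations.

The same stages are available as a CLI:

```bash
wnet simulate --out sim/ --seed 1
wnet connectivity --recording sim/HC-001.npz --out matrices/
wnet run-all --out demo_run --seed 1
```

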