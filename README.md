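# orgscreen

Analysis of time-lapse, image-based drug screens on patient-derived tumor
organoids — written for labs that screen organoids in 384-well plates with
brightfield segmentation plus a dead-cell reporter dye, and want to go from
per-organoid area measurements to clinically interpretable response calls.

A single screen yields, for every organoid at every timepoint, its masked
brightfield area, the dead-signal (e.g. Cytotox Green) overlap with that
mask, the area of the invasive annulus around it, and brightness/texture
descriptors. `orgscreen` turns those tables into:

- **Control-anchored bulk response metrics.** Per well, the net live signal
  S(t) = Σ bf − Σ green is self-normalized to its first timepoint,
  F(t) = S(t)/S(t₀). With vehicle and staurosporine control anchors F̄_neg
  and F̄_pos, the package computes % viability, the growth-rate metric
  GR = 2^(log₂F / log₂F̄_neg) − 1, and the normalized drug response

  NDR = (2^(log₂F / log₂F̄_neg) − 1) / (1 − 2^(log₂F̄_pos / log₂F̄_neg)),

  which is exactly −1 when a well tracks the kill control, exactly 0 at
  stasis, and ≈ 1 for control-like growth — robust to seeding-density
  differences because every well is normalized to itself before anchoring.
  Dose series are summarized by a span-normalized trapezoidal AUC of NDR
  over log₁₀ concentration, AUC ratios between regimens, and a
  cytotoxic / mixed / cytostatic signature from joint (NDR, % cell death)
  thresholds.
- **Single-organoid response and invasion classes.** The fraction affected
  fa = green/bf classifies each organoid as resistant (< 0.15), sensitive
  (0.15–0.34) or highly sensitive (≥ 0.34); invasion is scored by the
  survival invasive area (inv − inv_green), the invasive fraction (inv/bf)
  and a configurable invasive flag, crossed with the resistant split into
  four quadrant categories.
- **Heterogeneity mapping and pseudotime.** Six standardized features per
  organoid-timepoint → permutation-selected informative PCs (Holm-adjusted
  parallel analysis) → t-SNE with perplexity ⌊√n⌋ → Louvain communities on
  a kNN graph (k = 1000 capped at n−1, complement-of-distance edge
  weights) → a minimum spanning tree over cluster centroids with forced
  terminal clusters, per-path and common pseudotime, and treatment-arm
  density along a chosen trajectory.
- **Exact small-cohort statistics.** Spearman rank correlations of
  organoid readouts with progression-free survival use full n! permutation
  enumeration for n ≤ 8 (the regime of real organoid cohorts), plus a
  signature-vs-clinical-response concordance table.
- **A seeded plate simulator.** A two-compartment (live/dead area)
  exponential-growth model with Hill dose effects, clone mixtures,
  treatment-dependent invasion induction, Poisson seeding and
  multiplicative log-normal noise plants known ground truth for every
  stage; four named scenarios cover cytotoxic, cytostatic, heterogeneous
  and invasion-inducing responses.

## Worked example

```python
from orgscreen import (default_scenarios, simulate_plate, organoid_states,
                       class_fractions)

measurements, layout, truth = simulate_plate(default_scenarios(seed=3)["heterogeneous"])
states = organoid_states(measurements, layout)
top = states[(states.time_h == 120) & (states.role == "treatment")
             & (states.total_conc == 480)]
print(class_fractions(top, ["regimen"]).iloc[0][["n_organoids", "frac_resistant",
                                                 "ratio_sens_res"]])
```

prints

```
n_organoids       372
frac_resistant    0.301
ratio_sens_res    2.32
```

— the per-organoid classifier recovers the planted 30% resistant subclone
(binomial accuracy over 372 organoids) that the well-level NDR averages
away. The scripts in `examples/` walk through each capability the same
way: simulating a screen, dose-response metrics and signatures,
single-organoid classes, the t-SNE/Louvain/pseudotime map (where the
paclitaxel-like arm dominates the invasive trajectory), and the exact
clinical correlation (n = 7 with one adjacent rank swap gives
ρ = 0.9643, exact two-sided p = 0.0028 = 14/5040).

A thin CLI wraps the pipeline: `orgscreen simulate|wellmetrics|singleorg|run`
(exit codes: 0 ok, 2 config error, 1 data error).

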