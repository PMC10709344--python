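# Methods

## Well-level response metrics

The well signal is the net live area S(t) = Σ bf_area − Σ green_area over
the well's organoids, and each well is self-normalized to its first
measurement, F(t) = S(t)/S(t₀). Self-normalization removes seeding-density
differences before any cross-well comparison. Control anchors are the
arithmetic mean (median by option, for robustness to a failed control
well) of the fold changes of the vehicle wells (F̄_neg) and staurosporine
2 µM wells (F̄_pos), per plate and timepoint.

Three normalizations are derived from the fold changes:

- % viability = 100·(F − F̄_pos)/(F̄_neg − F̄_pos), an affine rescale with
  vehicle at 100% and the kill control at 0%; without a positive control
  it falls back to 100·F/F̄_neg.
- GR = 2^(log₂F / log₂F̄_neg) − 1, the growth-rate-normalized metric: 1 for
  control-like growth, 0 for complete arrest, negative for net loss. It
  requires F̄_neg > 1; a non-growing control raises a flagged error rather
  than returning a misleading number, because the exponent changes sign
  when log₂F̄_neg < 0.
- NDR = (2^(log₂F / log₂F̄_neg) − 1) / (1 − 2^(log₂F̄_pos / log₂F̄_neg)).
  This is the unique rescaling of the GR transform that is exactly −1 when
  the treated well equals the positive control and exactly 0 at stasis,
  for any valid anchors; when the positive control is fully dead
  (F̄_pos → 0) a control-like well scores exactly 1. Values above 1 are
  flagged proliferative. These anchor identities are enforced by property
  tests over random anchors and are the contract of the implementation.

Dose-response curves of endpoint NDR over log₁₀ concentration are reduced
to a trapezoidal AUC divided by the log₁₀ span, so a constant curve has
AUC equal to that constant and AUCs are comparable across regimens with
different dose ranges. The AUC ratio (combination / alternative regimen)
reads < 1 as the combination adding benefit. Endpoint metrics default to
the final timepoint (120 h); kinetic variants return per-timepoint values.

Response signatures classify the endpoint (NDR, % cell death) pair, with
% cell death defined as 100·Σ green/Σ bf per well: cytotoxic if
NDR < −0.5 and death > 40%; mixed if death > 40% with NDR ≥ −0.5;
cytostatic if NDR ≥ 0 and death ≤ 40%; anything else (negative NDR
without measurable death) is labelled indeterminate so the classifier is
total. The mixed-range rule is stated this way because the source
material's printed inequality for the mixed class is not internally
consistent; the adopted reading keeps the three classes disjoint and
matches the described phenotype (near-zero NDR with high cell death).

## Single-organoid classification

The fraction affected fa = green_area/bf_area (clipped to [0, 1]) is
binned half-open: resistant [0, 0.15), sensitive [0.15, 0.34), highly
sensitive [0.34, 1]. The cut points are configurable; the half-open
convention partitions [0, 1] with no gaps, reconciling the two slightly
different printed ranges for the middle class. Organoids with
non-positive mask area are excluded (logged), never imputed. The
sensitive:resistant ratio pools sensitive + highly sensitive in the
numerator, treating the classification as a resistant-vs-affected
dichotomy for cohort-level readouts; it is reported as infinite (flagged)
when no organoid is resistant.

Invasion metrics: survival invasive area = inv_area − inv_green_area,
invasive fraction = inv_area/bf_area, kinetic sum invasive area
normalized to its t₀ value (switching to a +1 µm² pseudo-baseline,
flagged, when the t₀ sum is zero). The invasive flag defaults to
invasive fraction > 0.2: the printed threshold in the source text ("< 2")
contradicts how invasiveness is used there (it would label nearly every
organoid invasive, in the wrong direction), so the flag direction follows
usage and the value is an explicit, documented configuration default.

## Heterogeneity map

Observations are organoid × timepoint rows over six features (area,
invasive area, fraction affected, invasive fraction, brightness,
texture), centered and scaled to unit variance; rows with missing
features are dropped and counted, constant columns excluded with a
warning. Informative PCs are selected by parallel analysis: each of
n_perm (default 1000) permutations shuffles every column independently,
the permutation p-value of a PC is (1 + #{permuted share ≥ observed})/
(1 + n_perm), p-values are Holm-adjusted in eigenvalue order, and
retention keeps the leading contiguous significant block. Note the
resolution constraint: with m features the smallest attainable Holm-
adjusted p is m/(n_perm + 1), so n_perm must exceed m/α − 1 (e.g. ≥ 120
at six features and α = 0.05) for anything to be retainable; tests use
n_perm = 200.

The retained scores are embedded by t-SNE (perplexity ⌊√n⌋, lowered to
⌊(n−1)/3⌋ with a warning when n is too small; fixed seed recorded). If no
PC is retained — pure-noise input — all standardized features are
embedded so the pipeline remains total. Clustering builds a kNN graph on
the embedding (k = 1000 capped at n−1), with edge weights the complement
of the Euclidean distance: since raw t-SNE distances are unbounded, the
complement is taken relative to the largest realized kNN edge,
w = 1 − d/d_max ∈ [0, 1] (w = d_max − d available by option). Louvain
community detection (seeded, resolution 1) labels clusters 1..C in order
of their smallest member index. Cluster profiles report mean
rank-normalized features (average ranks / n) and metadata enrichment
(within-cluster fraction / overall fraction); the root for trajectories
is the cluster most enriched for the earliest timepoint.

A note on small data: modularity maximization on a kNN graph whose k is
small relative to cluster size leaves dense disconnected components that
Louvain legitimately sub-splits. The k = min(1000, n−1) default avoids
this regime; with it, two well-separated planted blobs are recovered
exactly.

## Pseudotime

Cluster centroids in the embedding are joined by a Euclidean-weight
minimum spanning tree. Terminal states (resistant / sensitive / invasive
clusters, auto-selected from the rank profiles: max fa, min fa, and max
of the mean of invasive-fraction and invasive-area ranks) are *forced* to
be leaves: the MST is built over the non-terminal clusters first and each
terminal attached to its nearest non-terminal centroid. This
build-then-attach rule guarantees terminal degree 1 for any geometry; it
is one of several possible forcing mechanisms and is documented as such.

Each observation maps to the closest tree edge (orthogonal projection
clamped to the segment, ties to the lowest edge id). For each root→leaf
path, pseudotime is the arc distance from the root centroid to the
projection; observations on off-path edges are undefined for that path
and excluded rather than reassigned. Common pseudotime averages the
defined path values. Arm densities along a chosen path use a Gaussian
kernel with a single bandwidth (Scott's rule on the pooled on-path
values) shared across arms so curves are comparable, together with each
arm's on-path mass (fraction of its observations projecting to the
path).

## Exact clinical statistics

Spearman's ρ uses the classical 1 − 6Σd²/(n³−n) form for untied ranks and
the moment (Pearson-on-ranks) form with average ranks otherwise. For
untied data with n ≤ 8 the two-sided p-value enumerates all n!
permutations (#{|ρ*| ≥ |ρ|}/n!; 40,320 configurations at n = 8 are
instant); ties fall back to a seeded 10,000-draw Monte-Carlo permutation
p, larger n to the t approximation — the method is recorded on every
result. Censored patients are excluded from PFS correlations with a
reported count; no survival modeling is attempted. Signature concordance
maps cytotoxic→good, mixed→mixed, cytostatic→bad by default
(configurable) and reports the per-patient matches and overall fraction.

## The simulator

The generator emulates the statistical structure the analysis assumes,
not organoid biology in detail. Per organoid, with growth rate k (h⁻¹),
drug-dependent growth inhibition e and death rate δ (both Hill functions
of concentration, multi-compound doses combined by independent action):

- live area L(t) = A₀·e^{(k(1−e)−δ)t};
- dead debris D(t) = δ·∫₀ᵗL ds persists in the brightfield mask;
- emitted bf = L + D and green = D, so the net well signal is exactly L
  and the fraction affected D/(L+D) saturates at 1 under a killing dose;
- the invasive annulus is fed by live cells, inv(t) ∝ propensity ×
  induction × ∫₀ᵗL ds, with a per-compound induction factor (the
  paclitaxel-like arm carries factor 4) — a killed organoid stops
  invading, and the kill control's annulus stays negligible;
- brightness and texture are deterministic functions of the death
  fraction with the same multiplicative noise as the area channels.

Defaults, chosen once and stated as the simulated study conditions:
~200 organoids/well (Poisson), initial area log-normal around 2000 µm²
(log-sd 0.4), time grid 0–120 h in 24 h steps, two technical replicates,
multiplicative log-normal noise sd 0.05 per channel, clone doubling time
72 h, gemcitabine:paclitaxel doses at the fixed 5:1 molar ratio up to
400:80 nM, staurosporine 2 µM with death rate 0.2 h⁻¹ and full growth
arrest. The staurosporine rate matters numerically: it must be large
enough that the positive-control fold change is "fully dead" on the NDR
scale (F̄_pos ≈ e^{−24}) yet remain representable through the Σbf − Σgreen
float subtraction; 0.2 h⁻¹ satisfies both with margin at the default
growth rate.

What the simulator does **not** model — and hence what passing tests do
not establish about real screens: spatial well effects (edge evaporation,
optical vignetting), segmentation and tracking errors, organoid fusion
and fragmentation, drug pharmacokinetics or degradation, clone
interactions, and non-exponential growth. Recovery results (resistant
fractions to binomial accuracy; the invasion-inducing arm dominating the
invasive trajectory) demonstrate that the analysis chain is consistent
and identifies planted effects at realistic noise, not that it is robust
to artifacts outside the generative model.

## Problem sizes used in the test suite

Unit and property tests run on closed-form and small synthetic inputs.
The recovery suites simulate 50 seeds per condition: resistant-fraction
recovery at the full 200 organoids/well (single treatment well per seed),
and the invasion-trajectory comparison at 40 organoids/well with one
technical replicate (~1,900 observations/seed) with n_perm = 200 and
k = 100, sizes at which the map is stable while the full
t-SNE → Louvain → MST → density chain runs in a few seconds per seed.
The whole suite completes in about five minutes on one CPU.

## Known limitations

- The NDR closed form is anchored to the printed −1/0/1 scale; parity
  with any particular external implementation of the metric beyond those
  anchors is not asserted.
- Terminal forcing changes path membership relative to an unconstrained
  MST; only the chosen build-then-attach mechanism's outputs are
  guaranteed.
- Tied data make the exact Spearman path unavailable by construction; the
  Monte-Carlo fallback is seeded but approximate.
- Organoid identity across timepoints is trusted from the upstream
  platform; no track repair is attempted.
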