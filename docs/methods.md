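# Methods

## Estimators

**Per-block metrics.** Within a block that contains all three treatments,
CE = S̄_removal − S̄_control and CR = S̄_releasing − S̄_control, where S̄
is the arithmetic mean focal richness over the plot's sampling units at
the chosen scale (25 quadrats, 5 clusters, or the single plot unit).
Blocks lacking the removal treatment cannot anchor CE and are excluded
(`full_blocks`). Units with zero species contribute S = 0 to the means;
dropping them would bias both differences upward. Richness at the cluster
and plot scales is the count of species present anywhere in the unit (set
union over nested quadrats) — the only definition under which richness is
non-decreasing with area. With the balanced 5 × 5 design, averaging
quadrat richness directly over the 25 quadrats or first within clusters
gives the same number; the direct mean is used.

**Effectiveness.** Two estimators, as the framework intends:

* *mean of per-block ratios*: mean(CRᵦ/CEᵦ) with SE = sd/√n across blocks
  of one habitat × scale. The ratio is reported as undefined (NaN,
  excluded with a logged count) only when |CE| ≤ ε, ε = 10⁻⁹ species by
  default — near-zero-CE blocks produce wild but honest ratios, and
  suppressing them silently would bias summaries, so suppression beyond
  the numerical guard is opt-in.
* *compensation-line slope*: unweighted OLS of CR on CE pooled across
  habitats at one scale. Interpretation as effectiveness is conditional on
  the intercept not differing from zero, so the fit reports intercept and
  slope with SEs, R², and two-sided t tests (df = n − 2) of slope = 0,
  slope = 1 and intercept = 0. The signed t statistic for slope = 1 is
  included so a one-sided reading ("significantly below full
  compensation") is recoverable. On exactly collinear inputs the SEs are
  floating-point noise, so the fit reports SE = 0 and degenerate p-values
  (1 when the hypothesised value equals the estimate, else 0).

**Classification.** A point with CE > 0 is classified with tolerance δ
(default 0): `full` if |CR − CE| ≤ δ, `none` if |CR| ≤ δ,
`overcompensation` if CR > CE + δ, else `partial`. At δ = 0 this
partitions all CR ≥ 0 outcomes exhaustively and exclusively. Counting
"below the compensation line" is strict (CR < CE).

**Effect sizes.** LRR = log(S̄_treatment/S̄_control) per habitat × scale,
natural log by default (the convention of the response-ratio effect-size
literature; base 10 and 2 available since sources sometimes write "Log"
without a base). Means are taken over the full blocks only, so the removal
and releasing contrasts rest on the same blocks as the CR–CE analysis.
Nonpositive means raise rather than return ±∞.

## Composition analysis

Observation units are the clusters of full blocks, focal species only —
45 units per habitat in the reference design (3 blocks × 3 treatments ×
5 clusters). Pairwise Jaccard dissimilarity d = 1 − |A∩B|/|A∪B| is
computed on the presence sets (empty units are retained as units but must
be dropped, per flag, before dissimilarity — Jaccard is undefined between
empty sets).

NMDS is stress-majorization (SMACOF) with primary monotone regression:
each iteration fits isotonic disparities to the configuration distances
(ties in the dissimilarities averaged within tie blocks by PAVA),
evaluates Kruskal's stress-1 = √(Σ(d − d̂)²/Σd²), rescales the
disparities to a fixed norm (stress-1 is scale-invariant and unnormalised
updates shrink the configuration toward zero), and applies the Guttman
transform. Defaults: k = 2, 50 random starts (the first start from a
classical-MDS configuration), tolerance 10⁻⁶ on the stress decrease,
500 iterations; deterministic given a seed; the best start's
configuration, stress and stress history are returned, with
non-convergence flagged rather than raised.

**Centroid geometry.** The qualitative claim that the releasing
treatment's composition is intermediate — centroid closer to control than
the removal centroid is — is evaluated in the dissimilarity space itself:
squared centroid separation = mean between-group d² − ½(mean within-group
d² of each group), population form, clamped at zero. On
Euclidean-embeddable dissimilarities this equals the squared distance
between group centroids exactly. A 2-D NMDS embedding of 45 noisy Jaccard
units typically carries stress ≈ 0.3, at which the embedded centroid
ordering is unreliable, so the embedding is treated as visualization and
the check runs on the dissimilarities (embedding centroids remain
available via `treatment_centroids`).

## Synthetic experiments

The generator emulates a grazing/grass-removal grassland experiment: two
habitats ("valley" = high productivity, "slope" = low), each with 3 full
blocks and 4 partial blocks (34 plots total), 5 clusters × 5 quadrats per
plot, focal ("forb") and competitor ("grass") species groups. Occupancy
is independent Bernoulli per (species, quadrat):

* removal: p = π (baseline occupancy with competitors absent),
* control: p = π·c, with c ∈ [0, 1] the competitive survival multiplier,
* releasing: p = π·(c + e_true·(1 − c)),

so e_true = 0 makes releasing ≡ control and e_true = 1 makes releasing ≡
removal in distribution. Competitor species keep a fixed occupancy in all
treatments except removal (0 there): the releasing factor suppresses
competitors without eliminating them.

Defaults, chosen as realistic for a species-rich annual grassland and
fixed: 60 focal and 15 competitor species; π = 0.15 per quadrat;
competitor occupancy 0.45; e_true = 0.4; heterogeneous competition
c = linspace(0.05, 0.65) across focal species (mean 0.35) — species
differ in competitive tolerance, which is what gives the treatments
distinct *composition* rather than only distinct richness (with
exchangeable species the composition analysis would have nothing to
detect); habitat multipliers π × 0.6 and c × 1.5 on the slope, making the
low-productivity habitat sparser and less competitively structured. Under
these conditions expected richness per quadrat runs ≈ 3 (valley control)
to ≈ 9 (valley removal), and every habitat × scale expectation point lies
strictly below the compensation line.

**Oracles.** Under independence, expected richness of a unit of m
quadrats is Σᵢ(1 − (1 − pᵢ)ᵐ), m = 1/5/25, giving analytic CE, CR and
effectiveness per scale (`expected_richness`, `expected_crce`). At the
quadrat scale everything is linear in p, so CR/CE = e_true exactly, for
any heterogeneous π and c — the closed-form truth the recovery tests use.
At coarser scales the union nonlinearity moves the estimand away from
e_true, and `expected_crce` quantifies by how much.

**What the generator does not emulate.** Spatial aggregation and
species co-occurrence structure (occupancies are independent), block- and
plot-level environmental heterogeneity beyond the two habitat multipliers,
and treatment effects on competitor composition. Consequently the
synthetic plot scale — one sampling unit per treatment per block — is far
noisier relative to its expected CR–CE margin than replicated real
surveys tend to be: individual simulated plot-scale points can land above
the compensation line even though their expectations never do. Tests
therefore assert draw-level claims only at the replicated quadrat and
cluster scales and expectation-level claims elsewhere; passing them shows
the estimators are correct and well-calibrated under the stated sampling
model, not that any particular field system behaves this way.

## Problem sizes and numerical choices

The validation suite simulates the full 34-plot design for end-to-end
checks and reduced communities (≈ 8–30 species, full blocks only) for
Monte-Carlo calibration; recovery checks use 200 replicate simulations of
a reduced design to estimate the Monte-Carlo SE of the effectiveness
estimator and require agreement within 3 SE at e_true ∈ {0.2, 0.5, 0.8}.
NMDS examples and reports use 10–20 starts; all randomness flows from
explicit seeds. Identifiers are opaque strings (no numeric parsing of
block/plot labels); treatment and group vocabularies are canonicalised to
control/removal/releasing and focal/competitor via configurable maps, so
the framework is not tied to grazing systems. Design inference, metrics
and fits are invariant to row order and species relabeling.
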