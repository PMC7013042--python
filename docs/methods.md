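# Methods

This note documents the models and procedures implemented in `scfc`, the
defaults and why they were chosen, and what the synthetic validation does
and does not establish.

## Network construction

A structural edge between regions *i* and *j* exists when the streamline
count is at least `min_count` (default 3); its weight is
`count / (area_i + area_j)` with per-region surface areas in mm². Graph
metrics operate on the binary adjacency derived from positive weights; the
weighted matrix is used only by the coupling estimator (which is
rank-based, so any monotone reweighting of SC leaves coupling unchanged —
this is property-tested). Functional weights are Pearson correlations of
regional time series with negative values set to zero at construction, the
earliest point where downstream logic could observe them; zeroed entries
are consequently excluded from coupling masks by the strict `> 0` rule.
Both matrices are forced symmetric with a zero diagonal.

## Rich-club normalization

Φ(k) is computed for k = 1 … max degree − 1. Where fewer than two nodes
exceed *k*, Φ is **undefined and kept as NaN** on the aligned grid — never
dropped and never coerced to 0 — so per-subject curves can be compared at
identical *k* across a cohort.

The null model is the Maslov–Sneppen double-edge swap: 10 successful swaps
per edge, 100 surrogates per network by default (both exposed as
parameters). Connectedness is not enforced. Because surrogates preserve
the degree sequence exactly, the club at each *k* is the same node set in
every surrogate; only its internal edge count varies, which the
implementation exploits. Graphs admitting no valid swap (e.g. complete
graphs) yield surrogates equal to the source, with a warning, and
Φ_norm = 1 where defined. The swap kernel is JIT-compiled (numba) with a
behaviorally identical pure-Python fallback.

## Hub selection and edge classes

Hubs come from one consensus mean-degree profile across **all** subjects
of all groups, applied identically to every subject. Two rules are
implemented: `top_fraction` (the ⌈fraction·N⌉ highest-ranked regions, ties
at the cutoff broken lexicographically by label so selection is
deterministic) and `degree_threshold` (mean degree strictly above *k*; the
default, k = 10). A rule selecting no node or every node is an error.

Class densities divide by all unordered pairs N(N−1)/2 for every class, a
convention chosen so the three class densities sum exactly to network
density; class proportions divide by the number of present edges and sum
to 1. Both identities are asserted in tests on every generated subject.

## Coupling estimator

"Rescaled to a Gaussian distribution" is implemented as the rank-based
inverse-normal transform with the Blom offset, z = Φ⁻¹((r − 3/8)/(n + ¼)),
average ranks for ties; an all-tied input is an error because ranks carry
no information. The FC side is left raw. A scope's correlation is defined
only when its mask (SC > 0 ∧ FC > 0, intersected with the edge class) has
at least `min_edges` pairs (default 10 — correlations on smaller masks are
dominated by noise); in batch runs a too-small mask produces an explicit
`too_few_edges` row rather than a silent omission.

## Synthetic cohort generator

The generator emulates the statistical structure of a three-group aging
cohort on a 246-region parcellation (210 cortical + 36 subcortical), 43
planted hubs, group sizes NC = 38, MCI = 40, AD = 19.

**Structural model.** Pairs are Bernoulli with class-specific
probabilities `p_rich = 0.120`, `p_feeder = 0.0372`, `p_local = 0.0249`,
calibrated so a control network has ≈3.1% density, hub mean degree ≈12.6
(hub consensus degrees spanning roughly 9–19), and edge-class proportions
≈11.5% / 34.4% / 54.1% — the regime the analysis targets. The hub block is
**nested**: hub pair (i, j) receives probability `min(1, A·exp(−(i+j)/τ))`
with τ = `rich_nesting · n_hubs` (default 0.5·43) and A solved so the
block average is exactly `p_rich`. A flat block would fail to be a rich
club at the top of the degree range — among the very highest-degree nodes
the configuration-model expectation d_i·d_j/2E overtakes any constant
density — whereas the nested core keeps Φ_norm above 1 across the hub
degree span, as in empirical connectomes where the club core approaches
saturation. Disease groups thin each class by keep fractions (defaults:
MCI 0.90/0.90/0.97, AD 0.85/0.85/0.95 for feeder/local/rich), encoding
preferential feeder/local loss with relative sparing of the club. Present
edges carry counts `3 + Geometric(0.2) − 1` (support starts at the
streamline threshold; the count distribution is otherwise unconstrained by
the analysis) and regions get log-normal surface areas (median 800 mm²,
σ_log = 0.4).

**Functional model.** For structurally connected pairs,
`FC = Φ((ρ·z(SC) + √(1−ρ²)·ε) / c)` where z is the same Blom transform the
estimator uses, ε is standard Gaussian noise, and Φ(·/c) is a monotone
squash into (0, 1) with scale c = 3. The squash attenuates the Pearson
correlation by √(u/arcsin u), u = 1/(1+c²) — about 0.1% at c = 3 — so the
recovered coupling is essentially the generative ρ (defaults 0.30 / 0.40 /
0.50 for NC / MCI / AD, rising with disease stage). A fraction (default
0.10) of connected-pair draws is zeroed, mimicking negative correlations
zeroed at construction; unconnected pairs receive background
`min(|N(0, 0.15)|, 1)`, since functional connectivity exists without a
direct structural link. The background scale is a separate parameter from
the latent noise SD: the latent noise must stay unit-scale for ρ to be
recoverable, while a unit-scale background would be unrealistically
strong.

**Clinical model.** Age, education, and sex are drawn per group from
normal/Bernoulli models; clinical scores follow
`group mean + b_f·(feeder density − E[density]) + b_c·(coupling −
E[coupling]) + noise`, with the centering terms computed analytically so
group means hit their configured targets in expectation. The configured
dispersions treat published "±" figures as standard errors and convert to
SDs via SE·√n (a 1.6-year age dispersion over n = 38 is implausible as an
SD). The linear score model is a stand-in for an unknown generative
relation between disease stage, connectivity, and cognition; its loadings
make planted brain–behavior associations recoverable by the partial
correlation machinery, nothing more.

**Reproducibility.** One global integer seed; each subject's substream is
derived from a SHA-256 hash of (seed, subject id), so cohorts are
byte-identical across runs and independent of generation order.

## Statistical layer

Group comparisons fit `outcome ~ group + age + sex + education` by least
squares and test the group factor against the covariate-only model
(Type-II sum of squares; identical to Type III here since there are no
interactions). Adjusted group means are model predictions at covariate
means; the three pairwise contrasts carry Bonferroni-adjusted p-values.
Sex enters as a single indicator, education in years as a linear term; all
tests are two-sided. Per-*k* curve tests drop subjects with undefined Φ at
that *k*, record the per-*k* n, and Bonferroni-correct over the number of
*k* actually tested. Partial correlations residualize both variables on an
intercept plus covariates and use the t transform with n − k − 2 degrees
of freedom. Coupling values enter group statistics as raw r; a Fisher
variance-stabilizing transform is deliberately not applied (at the
moderate correlations and mask sizes involved it is nearly linear), and
all reports state the scale as raw r.
The chi-square test for sex is Pearson's, without continuity
correction, and requires an at-least-2×2 table of observed levels.

One caveat discovered while testing: with covariates orthogonalized
against the group factor and the outcome, ANCOVA's group and residual sums
of squares equal one-way ANOVA's exactly, but the F statistics differ by
the residual degrees of freedom absorbed by the covariates; the exact
identity (on sums of squares) is what the suite asserts.

## Validation design and problem sizes

The validation suite regenerates everything from scratch at these sizes,
chosen to keep Monte-Carlo error well below the margins being asserted:

- **Planted rich club:** 50 control-like networks, 100 nulls each. The
  "planted hub degree range" is the 10th–90th percentile span of the
  planted hubs' degrees pooled over replicates (the absolute min/max of a
  random draw would occasionally reach degrees where the club is nearly
  the whole network or nearly empty, regimes that measure nothing about
  the club). The seed-mean Φ_norm stays above 1 throughout this range;
  its minimum (≈1.02–1.03, at the low-k end where the club is most
  diluted by non-hubs) is the headline reproduction value.
- **Erdős–Rényi control:** 50 G(100, 0.1) graphs, 100 nulls each; the
  mean curve stays within ±0.1 of 1 over every *k* whose club averages at
  least 10 members. Below that size Φ is a ratio of tiny counts and its
  cross-instance mean is noise-dominated; those *k* are reported but not
  summarized.
- **Coupling recovery:** ρ ∈ {0, 0.3, 0.5}, 100 replicate subjects each
  at full 246-node scale; |mean bias| < 0.05 (observed ≲0.015).
- **Detection power:** 100 full-size cohorts; the planted feeder-density
  reduction is detected (group p < 0.05) in ≥80% of them (observed ≈100%,
  as the planted effect is large relative to binomial edge-count noise).
- **Type-I error:** 1000 reduced-size cohorts (13/13/7) with pure-noise
  outcomes; rejection rate within 3 Monte-Carlo SEs of 0.05.
- **Oracles:** shortest-path/efficiency metrics against a brute-force
  Floyd–Warshall implementation and Φ against exhaustive edge counting on
  100 random graphs of ≤30 nodes; ANCOVA and partial correlations against
  pingouin on simulated cohorts.

## What the synthetic data do not emulate

The generator reproduces the *statistical* structure the pipeline assumes,
not brain biology: there is no spatial embedding or distance-dependent
connectivity, no hemispheric symmetry, no modular/community structure
beyond the hub block, no tractography biases (length/curvature-dependent
streamline loss), no regional BOLD time series (FC is drawn directly), no
indirect-path contributions to FC, and no site or scanner effects.
Passing tests therefore demonstrate that the estimators and tests recover
what they claim from data satisfying their assumptions — not that those
assumptions hold in any particular empirical dataset. Weighted rich-club
variants, FC threshold sweeps, and edgewise inference (e.g.
network-based statistics) are out of scope.
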