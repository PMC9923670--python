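# Methods

## The statistical model

**Metabolic connectivity.** Regional uptake is treated as a random
vector over subjects; connectivity between regions i and j is the
Spearman rank correlation ρ_ij computed across the subjects of one
group, giving a symmetric R × R matrix with unit diagonal per group
(R = 28 for the default atlas). Rank correlation is used because
regional uptake ratios are bounded, often skewed, and monotone
transformations of the underlying physiology should not change the
inferred coupling — `spearman_matrix` is invariant under any strictly
monotone per-region transform.

**Edge comparison.** Correlations are variance-stabilised with the
Fisher transform z = arctanh(ρ) and compared between groups with
Z = (z₁ − z₂)/√(1/(n₁−3) + 1/(n₂−3)), two-sided p = 2Φ(−|Z|), and
Benjamini–Hochberg FDR across the R(R−1)/2 edges of one contrast
(per-contrast family; the sign convention is first-named group minus
second). The 1/(n−3) variance is exact only for Pearson correlations
of Gaussian data; for Spearman-based z it is conventionally inflated by
~1.06, available via `compare_groups(..., variance_inflation=1.06)`.
The default follows the plain formula, which is the form used in
covariance-connectivity practice. |ρ| is clamped at 1 − 1e−7 before the
transform so that perfect rank correlations — routine at n ≤ 8 — stay
finite (z ≈ 8.48).

*Small-sample caveat.* At n = 8 per group the normal approximation has
a heavy discrete tail: exact enumeration of the rank-permutation null
shows P(p < 2.6e−5) ≈ 3.5e−4 per edge, so with 378 edges a global-null
cohort pair produces at least one FDR discovery at q < 0.01 in roughly
10–30 % of replicates (depending on the inter-regional dependence).
This is a property of the method at that sample size, not of the
implementation; the acceptance suite measures it honestly rather than
hiding it. Edge-level findings at n ≤ 8 should be read as descriptive.

**Topology.** Graphs are weighted and undirected. Because shortest
paths are undefined for negative weights, the metrics operate on the
absolute-value or thresholded graph; the signed graph is kept for
edge-level display. Node degree is the unweighted suprathreshold
incident-edge count (weighted strength is available separately);
betweenness centrality is the normalised fraction of shortest paths
through a node with distance = 1/weight (Brandes accumulation, exact
path multiplicities); local efficiency of node v is the mean inverse
shortest-path distance, binary convention, within the subgraph induced
by v's neighbours (0 for fewer than two neighbours, 1 for a clique).

**Permutation testing.** Group-level matrices admit no subject-level
metric, so group labels — not metric values — are permuted: each
shuffle reassigns subjects to groups, recomputes both Spearman
matrices, rebuilds the graphs and recomputes the metric. Two-sided
add-one p = (1 + #{|null| ≥ |obs|})/(n_perm + 1), floored at
1/(n_perm + 1). Default n_perm = 5000; the seed is mandatory.

**Factorial ANOVA.** The split-plot decomposition tests the
between-subject effect against subjects-within-groups and the
within-subject and interaction effects against the subject-by-within
residual. Bootstrap p-values rebuild each effect's null as
(reduced fixed-effects fit without that effect) + (resampled
subject-level residuals) + (resampled within-subject residuals) — the
design's two error strata — and recompute F; classical parametric
p-values are reported alongside, and the two agree to ~0.01–0.02 on
balanced Gaussian data. Case resampling is available as an alternative
(`scheme="case"`). Šidák adjustment 1 − (1−p)^m covers the pairwise
contrasts of one ANOVA.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.01 | edge FDR level (q < α marks an edge significant) |
| `graph_scheme` | `thresholded` | edge rule for topology: `signed_rho`, `abs_rho`, or `thresholded` |
| `graph_threshold` | 0.5 | keep edges with \|ρ\| ≥ t; also `"significant"` (own-group p < 0.05) or `("top_k", k)` for density matching |
| `n_perm` | 5000 (pipeline 1000) | permutations per metric test |
| `n_boot` | 10000 | bootstrap resamples per ANOVA |
| `half_life_min` | 109.8 | ¹⁸F physical half-life for decay correction |
| `tissue_density_g_per_cc` | 1.0 | soft-tissue convention for %ID/g |
| seed | mandatory | every stochastic routine takes an explicit seed |

The 0.5 degree threshold is a package choice: it sits well above the
sampling noise of rank correlations at the n = 8–30 range this tool
targets while keeping block-level edges (ρ ≈ 0.5–0.65). Published
studies rarely state their thresholding rule; all three rules are
exposed and the one used is recorded in the graph metadata and output.

## The synthetic-data generator

Cohorts are drawn from a multivariate Gaussian whose correlation matrix
is assembled from Spearman-scale targets: a block pattern (within-
cortical, within-subcortical, cortico-subcortical — default
0.5/0.5/−0.3, the qualitative pattern of baseline cortico-subcortical
antagonism seen in lesion-model cohorts), optional baseline edge
overrides, and lesion-effect overrides applied to lesioned groups, with
a treatment fraction interpolating lesioned groups back toward
baseline. Spearman targets are converted to the generating Pearson
correlations with the exact Gaussian link r_P = 2 sin(π r_S/6), so the
Spearman stage recovers the configured values at large n (verified to
±0.05 at n = 5000). Override-laden targets can be slightly indefinite;
they are repaired by eigenvalue clipping (tolerance 1e−8) with the
Frobenius repair distance reported, and generation fails loudly if the
repair exceeds a configurable bound — a strongly wired hub over a weak
background, for instance, is geometrically infeasible (a hub
correlation h forces neighbour correlations ≳ h²), and silently
"repairing" it away would fake the intended ground truth.

Default study conditions mirror a four-group design (pre_VEH, pre_MLK,
QA_VEH, QA_MLK; n = 8 per group): the lesion lowers right-striatal and
right motor/somatosensory/orbitofrontal uptake and strengthens the
right frontal–somatosensory, frontal–motor and two cross-block edges;
treatment reverts 80 % of both. Effect magnitudes are illustrative
config values, not estimates from data.

Two packaged power scenarios carry known truth: `injected_edge_config`
(one edge at ρ = 0.8 in one group, 0 in the other, n = 30/group) and
`hub_degradation_config` (baseline hub at ρ = 0.75 over uniform 0.6
background, severed in the degraded group, n = 20/group; degree
threshold 0.55 — midway between the pooled-null hub coupling and the
baseline coupling).

What the generator does **not** emulate: scanner physics, noise
texture, attenuation, reconstruction artifacts, partial-volume effects,
inter-regional heteroscedasticity, or non-Gaussian tails. Phantoms are
noiseless labelled boxes; IFL images are noiseless two-level fields
with an exact bright-pixel count. Passing tests therefore demonstrate
the correctness and calibration of the *statistical chain*, not
robustness to acquisition artifacts.

## Numerical choices

- Spearman: average ranks for ties; Pearson on ranks; constant regions
  yield NaN edges plus an explicit flag, never silent zeros, and are
  excluded from both testing and the FDR multiplicity count.
- Fisher clamp 1 − 1e−7; decay round trip exact to 1e−12; threshold
  comparisons for pixel counting are strictly-greater-than so counts
  are bit-stable.
- Degenerate inputs fail loudly with the offending subject/group/label
  named: n ≤ 3 groups (the n − 3 variance), non-positive whole-brain
  means, overlapping phantom labels, grid mismatches. An all-edges-
  removed threshold yields an empty graph with a warning, not an error.
- Pipeline stage seeds are `sha256(master:stage) mod 2³¹`, so stages
  can be re-run in isolation; identical configs reproduce identical
  output checksums (asserted in tests).
- Zero mean squares in ANOVA (constant data) give F = 0, not NaN.

## Known limitations

- The edge Z test inherits the anti-conservatism described above at
  very small n; an exact rank-permutation edge test would control it
  but is not the method under study.
- Detecting a single injected edge of ρ = 0.8 vs 0 at q < 0.01 among
  378 edges needs |Z| > 4.2 while the effect supplies E[Z] ≈ 4.0 at
  n = 30/group, capping power near 0.45 regardless of implementation;
  the same edge is the *smallest-q* edge in >80 % of replicates.
- The permutation null for topology metrics widens when the tested
  effect is itself large (label mixing spreads the effect into the
  null), which is intrinsic to label permutation on group-level
  statistics.
- One-way bootstrap resamples pooled residuals and assumes exchangeable
  group variances under the null.
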