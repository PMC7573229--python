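# Methods

## Comprehensive tolerance evaluation

The screening model treats low-K tolerance as a latent property expressed
through many correlated trait responses. Its observable is the low-K
tolerance coefficient, the ratio of a genotype's treatment-mean trait value
under low K to its control mean; replicate means are taken per genotype
first, then the ratio (a coefficient above 1 is allowed and expected for
K-utilization-efficiency traits, which rise under deficiency, and such
traits are deliberately not inverted before PCA). The coefficient matrix is
column-standardized (sd with the n−1 denominator), so the PCA operates on
the correlation structure of the coefficients; eigenstructure is obtained
from an SVD of the standardized matrix, which is numerically preferable to
forming the correlation matrix explicitly. Contribution rates are
P_j = 100·λ_j/Σλ, and the retained component scores are the "comprehensive
indices".

Because the membership function is not sign-invariant, component signs must
be pinned: each loading vector is flipped so that its largest-magnitude
entry is positive, with magnitude ties broken at the lowest index inside a
1e-9 relative tolerance (exact-tie cases, e.g. two traits with ±0.7071
loadings, are otherwise decided by floating-point noise). The convention is
recorded in every run manifest.

Membership, weights and D are the exact textbook chain:
U_j = (X_j − min)/(max − min) per component over genotypes,
W_j = P_j/ΣP_j over retained components, D = Σ U_j W_j. The implementation
asserts ΣW = 1 (±1e-9), U ∈ [0,1], D ∈ [0,1] on every run, and D is
monotone under componentwise dominance of U by construction.

**Component retention.** Default is the Kaiser rule (eigenvalue > 1, never
fewer than one component); a cumulative-contribution threshold and a fixed
count are available. On synthetic panels driven by a single latent factor
the first component dominates and Kaiser typically retains one component —
real multi-trait panels with several independent response axes retain more.

**Classification.** Agglomerative hierarchical clustering on the
one-dimensional D values, Euclidean distance, average linkage (emulating
common SPSS defaults; Ward is a config switch), cut at k = 4 and labeled
tolerant → sensitive by descending class mean D. All D equal is rejected as
degenerate. **Extreme selection** uses empirical percentiles with linear
(type-7) interpolation and strict inequalities, so `lower_pct=0` selects
nothing; the convention is pinned for reproducibility. Cross-stage
consensus is a set intersection per direction with per-stage membership
flags, computed on the union of universes (a mismatch is warned about, not
fatal).

## Ionome arithmetic

Percent change is (LK − CK)/CK × 100 per (tissue, genotype, element),
retained at full precision with a 2-decimal reporting column (narrative
precision); zero-control or missing-treatment cells are flagged, never
fabricated. The reverse change satisfies (1 + pc₁/100)(1 + pc₂/100) = 1,
which the tests assert in place of (false) antisymmetry. K content is
DW [mg] × concentration [g/kg] × 10⁻³ in mg/plant, with strict unit labels.
KUE defaults to DW²/K-content (mg² per µg), the only form consistent with
the squared-dry-weight unit convention of such utilization indices; a
linear DW/K-content form sits behind `formula="linear"` because the
primary source for the exact formula is not available. Population means of
per-genotype products do not equal products of population means, so summary
tables cannot be used to validate the K-content formula beyond direction
and order of magnitude. Significance letters in concentration tables are
parsed and carried as annotations only.

## OPLS-DA and the metabolite screen

Preprocessing defaults to log transform followed by mean-centering and
unit-variance scaling (standard for MS intensity data and bounding the
influence of high-abundance features); Pareto scaling is a config option.
The class vector is ±1 (classes sorted lexicographically, the second class
coded +1) and centered. With a single response column the PLS weight has
the closed form w ∝ Xᵀy, so no iteration is needed and the fit is exactly
deterministic; each orthogonal component removes the part of the X loading
orthogonal to w (Trygg–Wold style deflation) before the predictive
component is refit. Orthogonality of predictive and orthogonal scores holds
to 1e-8 and is asserted on every fit. Requesting more orthogonal components
than the deflated matrix supports raises rather than returning noise.

VIP is computed from the predictive component only (the common OPLS-DA
convention — orthogonal variation carries no class information); with one
predictive component and a unit-norm weight vector VIP_j = √p·|w_j|, making
the mean of VIP² identically 1, asserted at 1e-6. Fold change is the ratio
of raw (unlogged) group means, matching how "n-fold" changes are reported;
a zero control mean yields an explicit +inf. The differential gate is
VIP ≥ 1 together with FC ≥ 2 or ≤ 0.5. Default n_orthogonal is 1. A
permutation diagnostic (label shuffles, default 100) is provided to show
the predictive explained Y-variance collapses without real class structure.

## DEG set algebra

Direction calls use |log2 FC| ≥ θ (inclusive boundary by default — the
threshold value itself counts; an exclusive switch exists because usage
varies) with raw p < α (no multiplicity adjustment by default; a BH flag is
available but off, matching the plain-p convention of threshold screens).
θ = 1, α = 0.05 by default. The two contrasts are crossed into the full 3×3
direction-pair table, whose cells sum to the gene universe by construction;
Venn counts are marginal sums of that table. Genes present in only one
contrast are treated as unchanged in the other, with a logged count. The
pattern-selection rule keeps the union (up, down) ∪ (up, unchanged) ∪
(unchanged, down) over the (tolerant, sensitive) pair — genes induced in
the tolerant genotype but not the sensitive one, or repressed only in the
sensitive one. Raising θ or lowering α can never increase a DEG count
(tested as a property).

## Synthetic-data generators

The generators emulate the statistical structure the pipeline assumes, not
the biology producing it.

*Trait panels.* Thirteen seedling traits with control means, genotype-level
CVs and mean LK/CK ratios calibrated to a published 543-genotype hydroponic
panel. A per-genotype latent tolerance score z (standard normal, or drawn
from planted tiers) shifts each trait's LK/CK ratio affinely —
ratio_t(g) = r_t(1 + loading·dispersion·z_g), clipped positive — so the
link is monotone and recoverable. Replicate noise is Gaussian with sd equal
to `noise_sd` × the genotype's control mean, censored at zero (trait values
are nonnegative physical quantities). Defaults: 3 replicates, loading 0.8,
dispersion 0.15, noise 10%. The tiered variant plants 7/50/238/248
genotypes at latent centers 3.0/1.5/0.0/−1.2 with within-tier sd 0.25 —
tier separation far above the within-tier spread, so classification
recovery measures the pipeline, not luck.

*Ionome tables.* Control concentrations log-normal around element-typical
levels (CV 25%); the LK value is CK × a user-supplied multiplicative
effect, so planted percent changes are exact by construction.

*Metabolite matrices.* Log-normal intensities (log-mean ~ N(13, 1), log-sd
0.2 by default); planted features shift the second group's log-mean by
log(FC) with FC drawn from [2.5, 8] and inverted for a random half, so the
true group-mean ratio equals the planted FC in expectation. Fold-change
ranges intruding into the (0.5, 2) non-differential band are rejected.

*DEG tables.* Each gene draws a direction pair from a 9-way multinomial
(default: 18% responsive overall, most genes unchanged in both contrasts);
changed genes get |log2 FC| ∈ [1.5, 5] and p ~ U(0, 0.04), unchanged genes
|log2 FC| ≤ 0.5 and p ~ U(0.1, 1). p-values are generated consistently with
the planted direction rather than from a count model — only the threshold
screen consumes them, and differential-expression model fitting is outside
this package's scope.

What the generators do **not** emulate: genotype-by-environment structure,
trait-specific error distributions, correlated measurement error across
traits, compositional constraints among elements, metabolite-metabolite
correlation, and p-value/effect-size coupling from a real count model.
Passing recovery tests therefore demonstrates the estimators and set
algebra are correct under the assumed structure, not that the pipeline is
robust to real-data pathologies such as batch effects or heavy-tailed
noise.

## Problem sizes and numerical choices

Recovery studies run at the study's panel scale (543 genotypes × 13 traits
× 2 treatments × 3 replicates), with medians over 20 seeds for the
screening chain, 50 seeds for the metabolite screen, and 100 seeds × 10,000
genes for the set-algebra enumeration — all complete in seconds on one CPU.
PCA agreement with an independent correlation-matrix eigendecomposition is
required to 1e-8; score-vector orthogonality to 1e-8; weight normalization
to 1e-9; VIP normalization to 1e-6. The pipeline fans a single global seed
into independent per-stage substreams (recorded in the manifest, each below
2³¹) so stages can be rerun independently with stable results.

## Known limitations

- With one retained component the D value is an affine function of the
  first comprehensive index; multi-component behavior is exercised with
  synthetic multi-factor matrices rather than the single-factor panel.
- Average-linkage clustering on 1-D data can split a small extreme group
  when noise blurs the planted gap; the class counts are data-driven, not
  fixed quotas.
- The OPLS-DA implementation targets two classes with a single predictive
  component; multi-class discrimination is out of scope.
- Enrichment analysis, differential-expression model fitting, and any
  statistical testing of element differences are intentionally not
  implemented; the package consumes and produces the tables around them.
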