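# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish about behaviour on real data.

## Study design assumed

The pipeline targets a multi-mixture isobaric-label design: each TMT
mixture carries the subcellular fractions (default seven, from differential
centrifugation) of both genotypes (default WT and MUT) plus pooled
quality-control channels (SPQC, default two per mixture), for
7 × 2 + 2 = 16 channels. "Condition" always means genotype × fraction
(14 levels by default); "biological samples" excludes SPQC channels.

## Normalization and filtering

The stage order is fixed: contaminants → sample-loading (SL) within mixture
→ SPQC outlier-peptide filter → kNN imputation → unique-peptide sum
summarization → SL across mixtures → internal reference scaling (IRS) →
protein filters → protein outlier filter. SL and IRS do not commute, so the
order is part of the method and is recorded in each run's provenance log.

* **SL** scales every column of a scope (one mixture's channels, or all
  samples after summarization) so its total equals the arithmetic mean of
  the scope's pre-normalization totals. The mean (rather than, say, the
  maximum) preserves overall scale. Missing cells are ignored in totals and
  never altered.
* **SPQC peptide filter**: per mixture, peptides missing any SPQC value are
  dropped; the rest are placed into five equal-count bins by mean SPQC
  intensity, and a peptide whose SPQC log2 ratio lies more than 4 bin
  standard deviations from its bin mean is removed. With more than two SPQC
  replicates the statistic is the mean pairwise log2 ratio. A 1e-9 absolute
  guard (log2 units) prevents float rounding from firing the rule in a bin
  whose replicates are exactly reproducible (SD at machine epsilon).
* **kNN imputation** replaces a missing entry by the mean of the k (default
  10) nearest rows' values in that column; distance is the root-mean-square
  log2 difference over mutually observed columns, and only rows observed in
  the target column are candidates. SPQC columns contribute to distances
  but are never imputed, so the SPQC completeness rules stay meaningful.
  This rule is deliberately explicit rather than delegated to a generic
  imputer, because the candidate set and the distance scale are part of the
  pipeline's contract.
* **Summarization** sums the intensities of peptides mapping to exactly one
  accession; shared peptides contribute to no protein.
* **IRS** multiplies, per protein and mixture, all of that mixture's values
  by (geometric mean of the per-mixture SPQC geometric means) / (SPQC
  geometric mean within the mixture). Zero or missing SPQC values would
  poison the geometric mean, so such proteins are flagged, left unscaled,
  and subsequently removed by the SPQC-completeness filter.
* **Protein filters**: presence in ≥ 50% of biological samples, ≥ 2 unique
  peptides, complete SPQC. The protein outlier filter reuses the binned
  log-ratio rule on same-condition replicates across mixtures.

A compositional caveat: total-intensity normalization assumes the bulk of
the proteome is unchanged. When a sizeable fraction of proteins carries a
genotype effect (as in aggressive synthetic scenarios), SL transfers a small
opposite shift onto null proteins, and the module-level tests — whose
standard errors shrink with module size × samples — can flag these residual
shifts as significant. This is a property of the normalization model, not a
software artifact; interpretation of small module shifts should keep it in
mind. (The effect is negligible when, as in typical real data, well under a
tenth of the proteome responds.)

## Covariation network and modules

Correlation is Pearson on log2 intensities over biological samples (log2
matches the modelling scale and stabilizes variance; a flag exposes
linear-scale correlation). Negative correlations are clipped to zero before
enhancement by default (absolute value is available) because the diffusion
and the community-detection quality operate on a non-negative kernel.

Network Enhancement follows the published diffusion re-weighting: rows with
nonzero degree are row-normalized ('ave'), truncated to the k strongest
neighbours per row (k = min(20, ⌈n/10⌉) by default) and symmetrized, a
transition-field kernel T is built, and the eigenvalues of T are mapped
d → (1−α)d / (1−αd^order) with α = 0.9, order = 2; the result is rescaled
by the input degrees and clipped at zero. All steps act within connected
components, so disconnected blocks never exchange weight. The test suite
verifies the implementation against an independent transcription of the
same algorithm that evaluates the diffusion as
(1−α)·T·(I − αT^order)^{-1} instead of via an eigendecomposition.

Surprise is the asymptotic form S = m·KL(q‖⟨q⟩) (natural log, 0·log 0 = 0),
computed on the upper triangle with the diagonal ignored. Leiden
(leidenalg's Surprise partition) is run with `n_restarts` seeded restarts
(default 100; seeds are `seed + r`), keeping the partition with the highest
Surprise; module ids are relabeled M1, M2, … by descending size with ties
broken by first appearance, making results deterministic for a fixed
(graph, seed, restarts). No minimum module size is imposed.

The visualization threshold removes edges in ascending weight order
(deterministic tie-break by node names) and stops at the first edge whose
removal would disconnect the module subgraph; this maximizes the number of
removed edges, since deleting a superset of edges can never restore
connectivity. Node importance is weighted degree in the full module
subgraph.

## Mixed models and contrasts

Both inference levels are instances of one random-intercept model
y = Xβ + Zu + ε with a cell-means design over conditions: mixture is the
grouping factor at the protein level; protein is the grouping factor at the
module level (mixture is omitted there because, after SL + IRS, its
variance share is negligible). The covariance V = σ²I + σ_g²ZZ′ is block
diagonal, giving closed-form per-group inverses, and REML reduces to a
bounded 1-D optimization in λ = σ_g²/σ² (log-scale golden-section via
`scipy.optimize.minimize_scalar`, xatol 1e-10, λ ∈ [e⁻¹⁴, e¹⁴]); the λ = 0
boundary is always evaluated, and a boundary or single-group fit degrades
to OLS and is flagged (`ols_fallback`).

Contrasts are sum-to-zero vectors over condition means: per-fraction
MUT − WT, and the overall genotype effect with weights ±1/7 across
fractions (equal weighting; fractions are treated as equally informative).
The test statistic is t = lᵀβ̂ / √(lᵀĈl) with Ĉ = (XᵀV̂⁻¹X)⁻¹. Satterthwaite
degrees of freedom use the moment approximation
df = 2g²/(∇gᵀA∇g), g(θ) = lᵀC(θ)l, θ = (σ_g², σ²), with ∇g and the observed
REML information (A = H⁻¹) obtained by central finite differences (relative
step 1e-4). The df is clipped to [1, n−p]; at the boundary (σ_g² = 0) the
residual df is exact and is used directly. The engine reproduces R's
lmerTest to ~1e-5 on estimate, SE, df, t and p (verified in the test
suite), and collapses exactly onto the pooled two-sample t-test in the
single-group limit.

Multiplicity: Benjamini–Hochberg across proteins within each named contrast
family (each fraction separately, plus the overall family — a pooled option
is not provided because families answer different questions); Bonferroni
with k = number of modules for the module family.

Relative (sum-normalized) intensity is computed per protein within each
mixture's biological samples by default (a global scope is available), so
mixtures contribute comparable profiles; the 0–1 rescaling used for
plotting is exposed separately and never used for fitting.

## Hypergeometric enrichment

p = P(X ≥ overlap) from `scipy.stats.hypergeom.sf`, background = union of
clustered proteins and all (mapped) set members, with set members outside
the background discarded before counting. Zero-overlap pairs are still
tested (p = 1) so the Bonferroni denominator is the full modules × sets
grid; the denominator is recorded in every result row. Identifier mapping
is table-driven; there are no online lookups.

## BioID analysis

The label-free arm normalizes across runs (SL), then rescales each
protein's biological replicates so their mean equals the SPQC mean.
Fold-change is the back-transformed difference of group log2 means, the
model is a per-protein two-group OLS comparison (pooled variance, the
"simple linear model" appropriate to three runs per group), and enrichment
requires fold-change strictly greater than 4 together with BH FDR < 0.05.
The joint rule makes false positives on null data vanishingly rare, which
the suite checks empirically.

## Synthetic data generator

Peptide-level log2 intensity is
log2(grand_mean · profile[fraction]) + effect·1[MUT, member module]
+ mixture effect (N(0, σ_M²), per protein × mixture) + peptide ionization
offset (N(0,1), fixed per peptide) + N(0, σ_peptide²) noise; reported
intensity is 2^value times a per-channel loading factor. SPQC channels draw
from the same latent protein mean pooled over fractions, with no genotype
effect. Defaults: 3 mixtures × 16 channels, σ_peptide = 0.25, σ_M = 0.10,
loading factors 2^N(0, 0.2), intensity-dependent missingness with
probability `missing_rate_at_floor` (default 0.10) at the 5% log-intensity
floor decaying by half per log2 unit above it (a flat missing-at-random
regime is available via `mnar=False`; realized overall missingness is a few
percent), and gross SPQC outliers (rate 0.002) that multiply a single SPQC
replicate by 2^±8, giving the 4-SD filter planted positives.

The clustering benchmark generator (`simulate_profile_matrix`) plants
modules with mutually orthogonal unit-variance log2 profiles over the 14
conditions (QR of a centered Gaussian matrix) plus N(0, 0.5) protein noise,
yielding within-module correlations near 1/(1+σ²) ≈ 0.8 and between-module
correlations near zero. Orthogonality is constructed at the condition level
because up to 13 mutually near-orthogonal profiles exist there, whereas the
7-dimensional fraction space cannot hold 10.

What the synthetic data do **not** emulate: chromatographic fractionation,
isotopic impurity and reporter-ion interference, peptide-level FDR,
correlated missingness across peptides of a protein, and realistic
compositional sparsity of effects (planted effects cover whole modules).
Passing tests therefore establish the correctness of the computations and
the calibration of the statistics under the stated generative models, not
the biological fidelity of any particular real dataset.

## Problem sizes used in the checks

The automated checks run at deliberately moderate sizes chosen to make
Monte-Carlo error small relative to the tested tolerances: 1000 protein
fits for type-I error (binomial SE ≈ 0.007 at the 5% level), 60 replicate
modules of 30–60 proteins per planted shift for estimator bias (MC error
≈ 0.002 ≪ the 0.02 band), 20 seeds of the 300-protein clustering benchmark,
and exhaustive enumeration for the combinatorial components (hypergeometric
grid to background 20; edge-removal search on graphs to 8 nodes).

## Known limitations

* The Satterthwaite information matrix uses finite differences; for nearly
  singular fits the df falls back to the residual df rather than failing.
* IRS requires complete, positive SPQC data per protein; proteins failing
  this are excluded rather than partially scaled.
* The module model treats proteins as exchangeable random intercepts;
  within-module correlation structure beyond the shared condition profile
  is not modelled.
* Compositional bias of total-intensity normalization under dense effects,
  as discussed above.
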