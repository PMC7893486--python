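# Methods

## Model and procedure

The package treats "which genes distinguish the stress network" as a
two-group contrast repeated within each donor and pooled across donors.

**Mapping.** Samples carry MNI mm coordinates; the mask carries a NIfTI
affine A (0-based voxel index → mm). A sample at x is assigned the voxel
round(A⁻¹x), rounded half-to-even per axis so ties at voxel faces are
deterministic. Nearest-voxel assignment (rather than a radius search) is
used because the expression samples are assumed to sit on, or next to, the
imaging grid; a maximum-distance gate (default half the voxel diagonal)
rejects matches that would imply a sample farther from every voxel center
than geometry allows. Any jitter below half a voxel width per axis cannot
change an assignment, which is tested as an invariant. Samples mapping
outside the volume are out-of-network, not errors.

**Contrast scopes.** The main contrast restricts both sides to cortical
samples; a whole-brain variant drops the cerebellum (its transcriptome is an
outlier that would dominate the contrast) and additionally requires
|log2FC| > 1 for significance; per-region variants restrict to one structure
label. Donors with fewer than 2 in-network samples in scope are excluded
donor-wise, because effects and variances are per-donor quantities. Z-scores
are recomputed within each contrast scope, so that "rest of cortex" means
exactly the samples the contrast compares against; scoping the
standardization to the contrast is a deliberate choice where the convention
is otherwise ambiguous.

**Effects and pooling.** Per donor d and gene g, the effect is the raw mean
difference of z-scored expression, y = mean(in) − mean(out), with sampling
variance v = s²_in/n_in + s²_out/n_out (ddof = 1). The mean difference — not
a standardized mean difference with small-sample bias correction — is used
because per-donor z-scoring already places all donors on a common scale.
Donor effects are pooled per gene with the DerSimonian–Laird moment
estimator: τ̂² = max(0, (Q − (k−1))/C) with fixed-effect weights, then
random-effects weights 1/(v + τ̂²), a normal z test (two-sided; sidedness is
a convention, the estimator is symmetric), and a 95% CI at ±1.959964·SE.
With a single donor τ̂² = 0 and pooling reduces to that donor's effect.
Degenerate zero variances (constant groups) are floored at 1e-8 rather than
allowed to produce infinite weights. Fold changes cannot be derived from
z-scores, so log2FC is the same DL pooling applied to unstandardized
log2-scale mean differences; the sign convention is fixed as in-network
minus out-of-network everywhere.

**Multiplicity.** BH is applied across the genes of one contrast scope, and
separately within each enrichment collection (and over exactly the three
GR/MR tests). Defaults: BH p < 0.05, except the expression-background
over-representation analysis which defaults to BH p < 0.001, following the
stricter convention for ontology screens.

**Bootstrap.** Stability against the in/out sample imbalance is measured by
redrawing, B times, n cortex samples (default n = 111, matching the network
size) from the pooled cortex regardless of membership, and contrasting the
original in-network samples against the draw with the identical
z-score/DL/BH machinery. Draws are stratified across donors proportionally
to each donor's cortex sample count (largest-remainder allocation, without
replacement within donor) so every donor stays representable in every
iteration. The report gives the per-gene significance frequency, the
per-iteration overlap with a reference list, and the fraction of iterations
with at least one overlapping gene — three summaries, because "reproduced in
X% of iterations" is ambiguous between them.

**Enrichment.** Every claim is a 2×2 Fisher exact test over an explicit
universe with OR = ad/bc (OR = +inf when bc = 0 and ad > 0; 0 when ad = 0;
NA when both products vanish). One-sided ("greater") p-values are the
default since the claims are directional; two-sided is available by flag.
Universe semantics are explicit parameters: the whole measured transcriptome
for disease/target sets, the top-20%-by-cortical-expression background for
ontology-style screens (per-donor cortical means averaged with equal donor
weight, top ⌈0.2·G⌉ genes, ties broken by gene id), and the receptor or
neuropeptide lists for the trait odds ratios. The GR/MR target sets must be
disjoint; genes claimed by several sets are resolved to the joint GR∩MR set
with a warning.

**Single cell.** Each cluster is scored as Σ over query genes of
log10(cluster aggregate + 1), with the aggregate defaulting to the cluster
mean count: the mean (with pseudo-count) is stable across cluster sizes,
whereas raw sums scale with cell number; a sum mode is kept for audit.
Classes are compared with a two-sided Wilcoxon rank-sum test on cluster
scores — the cluster, not the cell, is the sampling unit — exact when the
combined cluster count is ≤ 20 and tie-free, otherwise the tie-corrected
normal approximation. Counts are used raw by default; per-cell normalization
is the caller's choice upstream.

## Synthetic data: what it does and does not emulate

`generate_atlas` draws x_{g,s,d} = μ_g + (β_g + u_{g,d})·1[s in-mask] + ε
with μ_g ~ N(6, 2²) (a broad log2-intensity baseline), β_g = δ for a random
10% of genes by default (δ = 0.8 z-units), u_{g,d} ~ N(0, τ_g²) with τ_g
uniform on [0, 0.3] so the τ² estimator is exercised from homogeneous to
moderately heterogeneous regimes, and ε ~ N(0, 1). Geometry: 2 mm isotropic
voxels in a 40³ volume; a centered cubic mask sized to the in-network sample
count; samples at distinct voxel centers with sub-half-voxel jitter.
Defaults mirror the study scale: 6 donors, 111 in-network and 1839
out-of-network samples, 2000 genes (the transcriptome scaled down 10× to
keep test runtimes in seconds); in-network samples are cortical, the
remainder split cortex / cerebellum / hippocampal formation 70/15/15.

Gene sets are drawn per gene with membership odds among planted genes equal
to a requested factor times the odds among the rest (solved for the two
inclusion probabilities at a target expected size), plus a 1203-gene
receptor universe tag list, a neuropeptide list, and disjoint GR/MR target
sets sized at 3.5% / 6.2% / 2.3% of the transcriptome, matching the relative
sizes of the published target sets. Single-cell counts are negative binomial
(dispersion 2) over 24 clusters in three classes, with planted-gene means
multiplied by 3 in glutamatergic clusters.

Deliberately not emulated: spatial autocorrelation of cortical expression,
probe-level microarray noise, donor-specific sample geometry, and realistic
single-cell library-size variation. Passing recovery tests therefore shows
the estimators do what they claim under the assumed sampling model — not
that the biological conclusions of any particular dataset are correct.

## Numerical choices

- Half-to-even rounding for voxel assignment; membership is order-invariant.
- Variance floor 1e-8 for constant groups; z = ±inf handled to p = 0.
- Zero-variance genes z-score to all-zeros and are flagged, not dropped.
- BH via the standard step-up; input order restored; never decreases a p.
- Exact Wilcoxon only for tie-free pooled samples (≤ 20 clusters); the
  exact-distribution convention is 2·min(lower tail, upper tail), capped.
- All generators and the bootstrap are pure functions of (config, seed);
  the pipeline derives stage-specific substreams from one seed, and reruns
  are byte-identical (logs carry no timestamps for this reason).
- Ties in the expression background are broken by gene id so the selection
  is deterministic.

## Known limitations

- The DL z-test is anti-conservative with few donors under real
  heterogeneity: at k = 6 and I² ≈ 35% the empirical size of the nominal
  5% test is ≈ 7%, and BH inherits the inflation (empirical FDR on the
  planted atlas ≈ 0.11 at nominal 0.05). This is a property of the
  estimator, not of the implementation — the implementation matches both an
  independent step-by-step oracle (to 1e-10) and the reference R
  implementation of the same estimator. Small-sample corrections
  (Knapp–Hartung, REML) are out of scope by design; consumers should read
  the gene list as enriched-for-signal rather than FDR-certified at 0.05.
- Sign conventions for published fold changes vary; this package fixes
  log2FC = in − out and documents it rather than matching any one table.
- The GR/MR enrichment p-values depend strongly on the universe, which is
  therefore an explicit parameter; published adjusted p-values for those
  tests are not reproducible from the published counts under the full
  measured transcriptome as universe.
- Mask-to-sample assignment assumes annotations already carry MNI mm
  coordinates on (or near) the mask grid; no registration is performed.
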