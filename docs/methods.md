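# Methods

This note documents the statistical models behind each `glknet` stage, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions.

## Target definition

Binding sites are ranked by site FDR (ascending), ties broken by descending
score and then genomic coordinate, so the top-*n* cut is deterministic. The
FDR bound (default 7.2×10⁻¹¹, strict `<`) is applied before the top-*n* cut.
A nuclear protein-coding gene is a candidate target iff any selected site
overlaps, by at least 1 bp, the half-open window
[gene.start − upstream, gene.end + downstream), default 1 kb on each side.
The window is symmetric in genomic coordinates regardless of strand: the
"upstream, inside, and downstream" phrasing describes a genomic window, and
nothing in the analysis depends on strand-aware asymmetry. All coordinates
are 0-based half-open internally; GFF3 and VCF conversion happens at the I/O
boundary.

## Expression processing

Order of operations: gene filter (nuclear protein-coding only) → library
filter (total counts strictly below the threshold dropped; default 10⁶,
configurable because synthetic libraries are small) → per-accession column
sums → normalization → optional row-centering ("relative" expression).

Normalization is median-of-ratios size factors with a shifted log2:
reference genes are those with no zero count, the per-gene geometric mean
across accessions is the reference profile, each accession's size factor is
the median ratio to that profile, and the normalized value is
log2(count/sf + 1). This deliberately replaces a full variance-stabilizing
transform: every downstream consumer (clustering, Welch contrasts, partial
correlations) operates on the log scale and is insensitive to the exact form
of variance stabilization, while median-of-ratios keeps the size-factor
semantics. The pseudocount of 1 maps zeros to zero. Multiplying one
accession's counts by k multiplies its size factor by ~k; the residual
global shift through the geometric-mean reference decays as log2(k)/n
accessions.

## Biclustering

Genes and accessions are clustered independently by agglomerative
hierarchical clustering on the relative expression of the target panel
(defaults: euclidean distance, complete linkage — the common heatmap
defaults; both exposed as options since the choice is not otherwise
determined). Trees are cut at a user-chosen k; the package never selects k
automatically. Cut labels are renumbered by decreasing cluster size, so
"cluster 1" is always the largest (the A2-like reference group downstream)
and group references are reproducible across runs. Agreement with planted or
external labelings is measured by the adjusted Rand index.

## Differential expression

Per-gene two-sided Welch t-tests on normalized log2 values, BH adjustment
across all tested genes, log2FC as the difference of group means on the log2
scale. Significance is the strict conjunction q < 0.01 and |log2FC| > 2.
With group sizes in the tens to hundreds the normal approximation is
adequate, which keeps the stage free of count-model dispersion estimation.
Degenerate genes (zero variance in both groups) get p = 1 when means agree;
a variance floor of 10⁻¹² otherwise.

## Association testing and consequence calling

The association statistic is the 2×2 allele-count Pearson chi-square without
continuity correction (the PLINK `--assoc` convention): each accession
contributes two alleles, heterozygotes one of each, missing genotypes
nothing. Monomorphic variants get χ² = 0, p = 1. No multiple-testing
correction is applied; the analysis thresholds raw p at 10⁻¹⁰ (strict), then
requires alt-allele frequency strictly above 0.25 in at least one group
(a `--minor` switch filters on minor-allele frequency instead), exonic
position, and finally an impact class. Counts surviving each filter are
reported as a cascade.

The consequence caller handles SNVs on genomes whose CDS coordinates and
sequence are both available: it splices the CDS (strand-aware,
reverse-complementing minus-strand genes), substitutes the alternate base
and translates the affected codon with the standard genetic code. New stop
where the reference codon is not a stop → stop_gained/HIGH; amino-acid
change → missense/MODERATE; silent → synonymous/LOW; genic but non-CDS →
other/MODIFIER; intergenic → noncoding/MODIFIER. Loss of a reference stop
codon falls outside these categories and is reported as other/HIGH. Indels
are tested for association but labeled other/MODIFIER — codon-level calling
for them is out of scope. A reference allele that contradicts the genome
sequence raises a data-integrity error rather than silently proceeding.

## Graphical Gaussian models

For an n×p panel (accessions × genes) the empirical correlations R are
shrunk toward the identity with the analytic optimal intensity
λ\* = Σ_{i<j} V̂ar(r_ij) / Σ_{i<j} r_ij², clipped to [0, 1], where the
sampling variance of each correlation is estimated from the standardized
data products. Partial correlations come from the inverse of
R\* = λI + (1 − λ)R: pcor_ij = −Ω_ij/√(Ω_ii Ω_jj). λ > 0 guarantees
invertibility at any n/p.

Edge significance uses the analytic null
f₀(r; κ) = (1 − r²)^((κ−3)/2) / B(½, (κ−1)/2), under which |r|² ~
Beta(½, (κ−1)/2); the two-sided p-value is the regularized incomplete beta
upper tail. κ (the effective null degrees of freedom) is fit to the observed
off-diagonal partial correlations by maximum likelihood, assuming the bulk
is null. Two numerical safeguards matter in practice:

* **Robust null fit.** A sparse set of true edges drags a plain ML fit
  toward a far-too-wide null (a planted 10-of-190 edge set moves κ̂ from
  ~1000 to ~95 at n = 1000, inflating every edge p-value). The fit therefore
  excludes values beyond the *fitted null's own* 99% absolute quantile and
  refits by truncated ML with that model-derived cut, iterating to
  convergence. Under a pure null this perturbs the estimate only through the
  corrected 1% tail mass (measured false-edge rate 0.050 at nominal 0.05,
  p = 20, n = 500, 50 panels); under contamination the true edges leave the
  fitting set within a few iterations.
* **Shrinkage cap for inference.** Under a pure null at moderate n the
  estimated λ\* reaches 1, making every partial correlation exactly 0 and
  the edge test degenerate. `build_network` caps the intensity used for
  inference at 0.95; edge p-values are scale-invariant once κ is refit, so
  the cap preserves calibration while keeping the test informative.

Edges with p below the network-wide threshold (default 0.05) form the edge
list, sorted by ascending p then descending |pcor|. No multiple-testing
correction on edges: the analysis design thresholds raw edge p-values
(0.05 network-wide, 0.01 in the focal neighborhood).

## Neighborhood and differential edges

Partial-correlation graphs are undirected, so the focal-gene neighborhood is
breadth-first expansion over p < 0.01 edges, default 5 steps, stopping early
at a fixpoint; "upstream" in the motivating analysis is treated as
rhetorical. For the between-group comparison, every gene pair significant in
the *reference* network (the larger, A2-like group) is paired with its
strength in the alternate network; pairs with |Δ| strictly above 0.2 are
flagged, sorted by |Δ|. Pairs significant only in the alternate network are
not reported (a documented non-goal). The full panel, not only the
neighborhood, is compared; the neighborhood subgraph is additionally
exported as SIF.

Strength is the *deattenuated* partial correlation pcor/(1 − λ). Shrinkage
biases every pcor by the factor (1 − λ), and λ differs between networks fit
at different sample sizes (80 vs 120 accessions in the default synthetic
study), which both compresses true strength differences below the 0.2 rule
and manufactures spurious differences on edges the groups share. Dividing
out each network's own shrinkage factor puts both networks on a common
scale; significance continues to use the shrunk pcors and fitted null.

## Group statistics

Climate tables carry 12 monthly values per accession and variable; the
per-accession summary is the arithmetic mean and sample SD (ddof = 1) over
months. Group contrasts are two-sided Welch t-tests (unequal group sizes and
variances are the norm here); the climate ranking reports raw p ascending
plus a BH q column. Photosynthesis parameters are contrasted across the two
light regimes within each group, unpaired by default with a paired option
(whether the motivating measurements were paired is not determinable, so
unpaired is the conservative default). Over-representation of category
labels is a one-sided hypergeometric upper tail with BH across labels.

## Synthetic data

The generator emits every input shape the pipeline consumes, with one RNG
stream per domain (genome, counts, genotypes, climate, photosynthesis,
sites) spawned from the master seed, so changing one domain's parameters
never reshuffles another's draws.

Toy genome: two nuclear chromosomes with single-exon genes of 900 bp (CDS
300 bp) at fixed 2 kb spacing, alternating strand, plus a small organellar
chromosome and a few non-coding genes to exercise the gene filter. Counts:
per-gene log-normal baselines (log2 mean 7, sd 1), per-accession biological
noise (sd 0.5 log2 units — the cross-accession variance structure is not
externally determined, so it is a config knob), negative-binomial sampling
(dispersion 0.1), library size factors log-uniform over a 4-fold range, two
libraries per accession, and 10% deliberately shallow libraries (depth ×
0.005, never both libraries of one accession). Differential genes are the
target panel, shifted ±de_log2fc (default 3) in group 2 with random signs.

Network genes are disjoint-pair edges: this makes the canonical precision
matrix (unit diagonal, −pcor off-diagonal) positive definite for any
|pcor| < 1 and the implied partial correlations exactly the planted values.
Their expression is the multivariate-normal latent draw added to the
baseline and converted to counts deterministically, so the planted partial
correlations survive normalization — pushing them through the count noise
would distort exactly the quantity the network stage estimates. Base edges
(pcor 0.5) are shared by all groups; differential edges exist only in the
largest group (the reference), with strength diff_edge_delta. The defaults
(base 0.5, delta 0.8) come from a power analysis of the shrinkage estimator:
at 80/120 accessions per group the (1 − λ) attenuation and ~0.1 sampling sd
make weaker planted deltas undetectable at the 0.2 flagging rule, and a
generator whose planted effects are invisible at its own sample size tests
nothing.

Genotypes are Hardy–Weinberg draws with 2% missingness. Causal variants get
group allele frequencies ~0.55 apart, with rejection sampling keeping the
*empirical* gap ≥ 0.45 (and null gaps < 0.35) so planted/unplanted status is
unambiguous at desk scale; a configurable subset is planted inside CDS as
stop-gain codon edits (CAA→TAA), the rest as missense edits (GCT→GAT), on
either strand. Climate is a seasonal sinusoid per variable; only the
solar-radiation amplitude differs by group (group-2 SD = srad_sd_ratio ×
group-1 SD, default 2). Photosynthesis values are Gaussian around realistic
levels (QY_max 0.80, NPQ_Lss 1.2, QY_Lss 0.55), with photo_interaction
(default +0.5) added to NPQ_Lss only in (group 2, inland/high-light).

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: linkage disequilibrium and kinship structure
(the association test is uncorrected for relatedness by design), multi-exon
and multi-isoform gene models, count overdispersion trends with expression
level, spatial climate correlation, and repeated-measures structure in the
photosynthesis table.

## Numerical conventions and limitations

All published-threshold comparisons are strict (`<` / `>`), including the
boundary cases: a library with exactly the minimum reads is retained; a
variant at exactly p = 10⁻¹⁰ or frequency 0.25 is excluded; an edge
difference of exactly 0.2 is not flagged; a fold change of exactly 2 is not
significant. Clustering ties in merge heights resolve by scipy's
deterministic leaf ordering; equal-size cluster ties relabel by first
occurrence. The κ search runs on log(κ − lower) over (3, 10⁷]; an all-zero
pcor set returns the upper bound and is logged as degenerate. Pipeline
artifact files are written with fixed float formats, so identical configs
and seeds produce byte-identical outputs; run wall times live only in the
run report.

Problem sizes used by the test suite and acceptance script (calibration at
p = 20 genes with n = 500–2000 samples over 20–50 replicates; cohorts of
200 accessions; 100–500 variants; 200 null DE panels) are the package's
desk-scale study conditions: large enough that every planted effect is
detectable with margin under the stated models, small enough to iterate on.
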