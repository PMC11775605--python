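# Methods

## Study design being modelled

The pipeline contrasts two reproductive modes of a cyclically
parthenogenetic aphid. The focal dataset holds 40 whole-body RNA-seq
libraries: 4 CP lineages × 3 morphs (male, sexual female,
parthenogenetic female) × 2 replicates, and 4 OP lineages × 2 morphs
(no sexual females) × 2 replicates. Morph- and tissue-bias classes are
called on *independent* reference data — a 6-library whole-body set
(3 morphs × 2 replicates) and an 18-library tissue set (3 morphs ×
3 tissues × 2 replicates) — so that the same libraries are never used
both to define gene classes and to measure shifts between modes.
Genetic structure comes from biallelic SNPs for the 8 lineages.

## Normalization

TMM follows the canonical algorithm: the reference library is the one
whose 0.75-quantile count fraction is closest to the mean of those
fractions; per-library log2 ratios against the reference are computed
over genes positive in both libraries, doubly trimmed (30 % of
M-values and 5 % of A-values from each tail) and combined with
inverse-variance weights from the binomial delta method; factors are
rescaled to geometric mean 1. The implementation agrees with the
reference implementation (edgeR `calcNormFactors`, TMM, p = 0.75) to
~5e-13 on a frozen 200 × 6 fixture (`tests/data/`). Expression
filtering keeps genes with CPM strictly above 1 in at least 8 focal
libraries (2 for the smaller reference sets). CPM averaging is
two-stage — replicates within lineage, then lineages within mode — and
is done on the CPM scale, because the shift statistic takes its log
after averaging.

## Differential expression and classification

With two replicates per group, genewise dispersions are not
identifiable, so a single common NB dispersion φ per dataset is
estimated by conditional maximum likelihood after equalizing library
sizes (mean-preserving proportional scaling to the geometric-mean
effective size; the classical quantile-to-quantile NB adjustment
coincides with this in the equal-size case the tests exercise). The
exact test conditions on the total pseudo-count: the group-A sum given
the total is beta-binomial (negative hypergeometric) with shapes
n_A/φ and n_B/φ, reducing to binomial(t, n_A/(n_A+n_B)) at φ = 0. The
two-sided p doubles the smaller inclusive tail, capped at 1. The
implementation is verified against exhaustive enumeration of the
conditional law for all totals ≤ 30 at φ ∈ {0, 0.1, 0.5}.

Counts are rounded to integers before exact testing (quantification
with fractional multi-mapper weights can produce fractional counts;
the conditional law needs integers). Fold-changes are computed from
CPM-scale group means with a proportional prior count (default 2 on
the count scale) to avoid log of zero; the prior is a config knob.

Classification uses strict inequalities (adjusted p < 0.05,
|log2FC| > 1, > 2 for "limited"), and requires consistent
overexpression in both of a morph's pairwise comparisons; ties at a
threshold therefore do not qualify. The same dual rule yields
tissue-bias labels within each morph. Labels are mutually exclusive by
construction (a gene cannot win both comparisons for two different
morphs). Because the original analyses were run with two releases of
the same DE tool whose defaults may drift slightly, the dispersion
treatment is exposed as a config switch; only common dispersion is
implemented.

## Shift statistic

Per gene and morph: `log2((mean_OP + ε)/(mean_CP + ε))` with
ε = 0.05 CPM. The pseudocount keeps ratios finite and shrinks
low-expression ratios towards zero; as ε grows all ratios tend to 0.
Class medians (*Mdn*) are tested against zero with a two-sided
Wilcoxon signed-rank test; zero ratios are dropped before testing
(standard treatment), the exact null distribution is used for n ≤ 25
and the continuity-corrected normal approximation otherwise (verified
to reproduce R `wilcox.test` p-values in both regimes). Subdivision
panels (degree, chromosome, tissue) restrict to genes carrying the
relevant key — tissue panels only include genes with a tissue-bias
call in their own bias morph. Robustness checks: all 4 × 4 OP–CP
pairwise-lineage medians, and a leave-one-out analysis that re-derives
classes from one held-out CP lineage's three morphs and recomputes the
shift from the remaining lineages.

## Genetic and transcriptomic divergence

SNPs are kept when genotype quality is strictly above 20 and depth at
least 80 in every library; only biallelic single-nucleotide records
qualify. Depth is interpreted per library per genotype. Allele
frequencies use dosage/2 — the natural estimate with one diploid
individual per clonal lineage, so a heterozygote contributes 0.5.
Nei's standard distance averages the identity probabilities across
loci before taking the log; disjoint allele sets yield an explicit
infinite distance. Neighbour joining is the Saitou–Nei agglomeration
(exact on additive matrices, checked by patristic reconstruction);
bootstrap support resamples loci with replacement (default 1000,
seeded). PCA operates on centered dosages; per-SNP scaling is a
switch, off by default.

Transcriptomic distances are Euclidean between replicate-averaged
lineage profiles within a morph after per-gene standardization.
"Standardization by gene" is implemented as z-scoring across the
compared lineages (center-only is a config switch); zero-variance
genes are dropped with a warning. Mantel tests use Spearman
correlation with seeded label permutations (default 999, one-sided
"greater", i.e. distances increase together). Mode divergence compares
the per-lineage mean distance to same-mode partners between the two
modes with an exact two-sided Mann-Whitney test (4 vs 4: 70 rank
configurations, minimum attainable two-sided p = 2/70 ≈ 0.029); the
genetic correction divides each pairwise transcriptomic distance by
the corresponding Nei distance before focal averaging.

## Synthetic data

Counts are negative binomial with mean
`μ_gs = w_gs / Σ_g w_gs × L_s`, where
`w_gs = baseline_g · 2^(morph effect + lineage effect + δ)` and L_s is
a log-normal library size; the compositional renormalization makes TMM
meaningful. Defaults (free parameters at desk scale, chosen once as
typical bulk RNA-seq values): baseline log2 expression
Normal(5, 2); dispersion log-normal with median 0.05 and σ = 0.4;
library sizes ~1.5 × 10⁶ with CV 0.15 (scaled well below real
sequencing depth so that the full design simulates in seconds);
10 % of genes per biased class, morph effect 2 (log2) for biased and
3.5 for limited genes (30 % of biased genes); half of biased genes get
a tissue bias (+2.5 log2 in that tissue of their bias morph); lineage
random effects Normal(0, 0.08) shared across a lineage's morphs
(clonal genotypes). X linkage is assigned independently of class at
30 % by default, with an optional enrichment knob for male-biased
genes. Injected OP-to-CP shifts δ apply to OP libraries of the target
morph and gene class only.

Genotypes drift hierarchically (ancestral → mode cluster → lineage,
frequencies clamped to [0, 1]); allele-copy draws share underlying
uniforms across lineages, so genotype differences reflect frequency
drift only and zero drift yields identical clones — this makes the
degenerate no-divergence case exactly zero-distance, at the cost of
slightly understating binomial sampling noise. Default drift SDs
(0.15 between modes, 0.05 within) give unambiguous mode structure;
the resulting Nei distances are smaller than typical empirical values
and should be read as scaled-down.

What the generator does **not** emulate: read-level artifacts,
fractional multi-mapper counts, gene–gene correlation (co-regulation)
within lineages, whole-body tissue composition, and realistic
population history. Two consequences matter for interpretation.
First, because lineage effects are independent across genes, distances
built from thousands of genes concentrate extremely tightly around
their expectations; the exact 4-vs-4 Mann-Whitney then resolves even
sub-percent systematic differences, so the simulated within-mode
transcriptomic comparison can reach its minimum p where real data
(with correlated biological variation) would not. Second, injecting
positive shifts inflates OP library totals, and CPM renormalization
passes a small negative offset (~0.01–0.02 log2) to unshifted genes —
an inherent property of compositional normalization, visible as
slightly negative unbiased-class medians. Recovery tests therefore
compare medians to injected values within the estimator's repeat-seed
sampling error rather than exactly.

## Numerical choices and degenerate inputs

All-zero libraries, constant genotype matrices, empty gene classes,
missing morphs/tissues and label mismatches raise errors naming the
offending object; empty subdivision levels are skipped with a warning;
genes missing from the chromosome annotation are labelled `unplaced`
with a warning count. The dispersion optimizer is bounded
(φ ∈ [1e-6, 20]) and returns exactly 0 at the lower boundary (Poisson
limit). Random streams are split per purpose (gene truth, focal
counts, outgroup, tissue, genotypes) from the user seed, so the focal
and reference datasets share gene-level ground truth and every output
is bit-reproducible under a fixed seed.

## Problem sizes

Default runs use 4 000 genes and 5 000 SNPs; the test suite uses
500–3 000 genes, 20-seed recovery runs and reduced bootstrap and
permutation counts. These sizes were chosen so the whole analysis runs
in well under a minute while keeping class sizes (~400 biased genes
per class) large enough for the median estimators to be informative.
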