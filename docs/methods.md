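# Methods

This note documents the statistical procedures implemented in
`culicinet`, the defaults and why they were chosen, the numerical
details that matter for reproducibility, and the limits of what the
synthetic benchmarks demonstrate.

## Pipeline order and normalizations

The network branch follows a fixed order per mosquito species: rarity
filter on ASVs → taxonomy collapse → percent relative abundance →
Spearman correlation → thresholding.  The diversity branch instead
rarefies the ASV table to a common depth (default: the minimum sample
total, configurable) before computing Shannon indices and UniFrac
distances.  The two branches deliberately use different normalizations:
rank correlations need compositional percentages, while richness-based
metrics need equal library sizes.

**Rarity filter.**  A taxon is removed when its summed reads over all
samples of the table being analyzed fall strictly below `min_fraction`
(default 0.001, i.e. 0.1 %) of that table's grand total.  "All samples"
is ambiguous when networks are built per species; the default scope is
per-species (each species' own grand total), with `filter_scope=global`
applying one filter to the pooled table first.  Per-species is the
default because every downstream correlation matrix is per-species, so
a taxon's relevance should be judged inside the group being analyzed.

**Taxonomy collapse.**  ASVs sharing a lineage down to genus are summed.
The grouping key is the full lineage prefix, not the bare genus string,
so homonymous genera under different families stay separate (SILVA
contains repeated genus labels).  ASVs unassigned at genus are kept,
pooled at their deepest assigned rank as "Unclassified <name>"; fully
unassigned ASVs pool into "Unassigned" (droppable by flag).  Collapse
conserves per-sample totals and is idempotent.

**Rarefaction.**  Without-replacement subsampling (multivariate
hypergeometric), never with replacement; samples shallower than the
target depth are dropped and reported.  Rarefaction curves average a
configurable number of independent draws (default 10) per depth.

## Alpha diversity

Shannon–Weaver uses log base 2 by default (the convention of common
amplicon pipelines; natural log available via `base`).  Between-species
comparison is Kruskal–Wallis with tie correction (the degenerate
all-identical case is defined as H = 0, p = 1) followed by Dunn's
z-tests on mean ranks with the tie-corrected large-sample standard
error and Bonferroni adjustment over all k(k−1)/2 pairs.  No exact
small-sample Dunn variant is provided.  Normality screening is not
reimplemented; the nonparametric route is the default and only omnibus.

## Beta diversity

UniFrac is computed on the rooted ASV phylogeny via scikit-bio.
Unweighted UniFrac is the fraction of branch length unique to one of
the two samples' leaf sets; weighted UniFrac defaults to the raw
(unnormalized) variant $\sum_b \ell_b\,|p_A(b) - p_B(b)|$, with the
[0, 1]-normalized variant behind a flag.  PCoA is classical scaling:
double-center $-\tfrac12 D^2$, eigendecompose, scale eigenvectors by
$\sqrt{\lambda}$; negative eigenvalues (non-Euclidean distances) are
reported but contribute no axes, and proportions of variance are taken
over the positive spectrum.

PERMANOVA computes the pseudo-F directly from the distance matrix
(no ordination), with
$p = (1 + \#\{F_\pi \ge F_{obs}\})/(1 + n_{perm})$ over seeded uniform
label permutations (default 999).  Every group needs at least two
samples.  The pairwise variant reruns each species pair on its
submatrix and reports raw and Bonferroni-adjusted p-values, since no
single adjustment convention dominates in practice.  Note the smallest
attainable p depends on group sizes: with very small balanced groups a
random permutation occasionally reproduces the observed split, so p
cannot reach $1/(n_{perm}+1)$.

## ANCOM

For each ordered taxon pair the additive log ratio (after adding a
pseudocount of 1) is tested across species with Kruskal–Wallis; within
each taxon's m−1 tests the Benjamini–Hochberg procedure is applied at
α = 0.05, W counts the rejections, and detection requires
W ≥ 0.7 (m−1).  The BH-within-taxon correction and the 0.7 fraction
follow the original ANCOM description; both are configurable.  Because
samples enter only through within-sample ratios, W is invariant to
per-sample library-size rescaling.  A caveat observed in calibration:
a rare taxon whose zeros happen to fall unevenly across groups shifts
*all* of its log ratios at once and can reach maximal W under a true
null; this happens in a few percent of null datasets and is inherent to
the W construction, not a defect of the test statistics.

## Interaction networks

Spearman's rho is the Pearson correlation of midranks (tie-corrected).
P-values are exact for n ≤ 8 — the full n! permutation distribution of
one rank vector, cached per pair of rank multisets so large tables stay
fast — because the smallest realistic species group (6 specimens) is
far outside the t-approximation's comfort zone.  For n > 8 the usual
$t = \rho\sqrt{(n-2)/(1-\rho^2)}$ with n−2 df is used; the two paths
agree within 0.02 at the n = 8 boundary.

Edges keep pairs with $|\rho| > 0.75$ **and** $p < 0.05$, both strict.
The absolute-value reading is the default because co-exclusion
(negative) edges are a central output; a literal positive-only
threshold is available via `use_abs=False`.  No multiple-testing
correction is applied to the correlation p-values by default —
matching common practice for these descriptive networks — but
`p_adjust="bh"` is available, and users should expect small groups to
produce many chance edges (at n = 6 the exact p of a perfectly
monotone pair is only 2/720 ≈ 0.003, and |ρ| > 0.75 is reached by
chance easily; compare the worked example in the README).  Zero-variance
taxa within a species are excluded from correlation (reported, not an
error).  Compositional closure can manufacture negative correlations;
this is documented rather than corrected (SparCC-style methods are out
of scope).

## Synthetic data generator

The generator emulates the shape of an 8-species field survey: group
sizes 8, 6, 7, 14, 15, 12, 30, 19 (111 samples), per-sample depths
uniform on [8857, 123070] reads, 300 ASVs with SILVA-style lineages
(10 % genus-unassigned, a few shared-genus ASV pairs), and a random
sequential-coalescence tree with exponential branch increments (adequate
for exercising UniFrac; no biological realism claimed).

Per sample: a latent standard-Gaussian vector carries the planted
associations (for each planted pair, the second coordinate is
$\rho z_i + \sqrt{1-\rho^2}\,z_j$ — a Gaussian copula); log-abundances
are the species base vector plus the latent vector; softmax gives the
composition; counts are Dirichlet-multinomial at the sample's depth.

Defaults, chosen once by design analysis:

- `base_sigma = 1.5`, `species_sigma = 1.0`: log-normal abundance
  spread and species-specific composition shifts large enough that
  species separate in beta diversity, as real mosquito species do.
- `overdispersion = 2000` (Dirichlet concentration): moderate
  overdispersion — variance inflation over the multinomial of roughly
  (depth + θ)/(θ + 1), i.e. a few-fold at the simulated depths.  Heavier
  overdispersion scrambles low-abundance ranks enough that even a
  latent ρ = 0.9 cannot clear the 0.75 edge threshold; this value keeps
  the planted-signal design coherent while remaining clearly
  non-multinomial.  The multinomial limit (`overdispersion=None`) is
  used for clean null calibrations.
- planted taxa sit at an elevated base (~5 % mean relative abundance,
  like the abundant genera that anchor real mosquito networks) so they
  survive the 0.1 % filter and their counting noise is small.
- default planted edges: six disjoint pairs with ρ = ±0.90…0.95.
  Closure (softmax) and rank-noise attenuate the realized Spearman by
  roughly 5–15 %, which is why planted magnitudes are generous; the
  n = 30 group recovers them with precision ≈ 1 and recall ≈ 0.9 at
  default thresholds, with all signs correct.
- three species-specific 100× differential taxa (named Wolbachia,
  Asaia, Afipia in the synthetic taxonomy) give the ANCOM stage a
  ground truth.

What passing these benchmarks does **not** show: the generator has no
chimeras, no contamination, no phylogenetic signal in abundances, no
spatial or temporal structure, and its taxonomy is synthetic — so the
tests validate the statistical machinery, not classifier quality or
real-data effect sizes.  Printed results of any particular field study
depend on its raw sequencing data and upstream denoising, which are out
of scope here.

## Determinism and numerics

One master seed; each stage derives its own seed from the CRC-32 of the
stage name, so adding a stage never shifts another stage's draws.  Two
runs with the same inputs, config and seed are byte-identical.  Exact
Spearman p-value comparisons use a 1e-12 slack on the ≥ comparison so
ties at the observed value are counted; strict threshold comparisons
(0.75, 0.05) are literal `>`/`<`.  PCoA treats eigenvalues below
1e-10 of the spectral radius as zero.  Problem sizes in the test suite
and acceptance script (e.g. 20–50 seeds for recovery, 500 replicates
for calibration, 200 random trees for the UniFrac oracle) were chosen
to keep Monte-Carlo error well inside the asserted margins.

## Known limitations

- ANCOM is the classic W-statistic form; ANCOM-BC/ALDEx2 effect-size
  models are not provided.
- No compositional correction of correlations (SparCC, SPIEC-EASI).
- Weighted UniFrac's raw variant is depth-sensitive; use it on rarefied
  tables (the pipeline does).
- Only TSV/BIOM-JSON v1 input; no BIOM-HDF5 or FASTQ handling.
- Plotting is intentionally absent: heatmap and ordination matrices are
  emitted as TSV for external viewers.
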