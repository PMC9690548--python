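# culicinet

Diversity statistics and signed bacterial co-occurrence networks for
multi-species mosquito (Culicidae) 16S rRNA amplicon surveys.

Field surveys of mosquito microbiota profile the V4 region of the
bacterial 16S gene in individual specimens from several host species,
then ask three questions: does alpha diversity differ between mosquito
species, do whole bacterial communities differ between species
(beta diversity), and which bacteria co-occur or exclude each other
*within* each species?  `culicinet` implements that downstream analysis
as a tested, reusable pipeline starting from the denoised ASV
(amplicon sequence variant) count table — the point where upstream tools
(read joining, denoising, taxonomic classification, tree building) leave
off.

## What it computes

Given a samples × ASVs count table, SILVA-style taxonomy, a sample →
mosquito-species map, and a rooted phylogeny of the ASVs:

- **Alpha diversity** — Shannon–Weaver index
  $H = -\sum_i p_i \log_2 p_i$ per sample on a rarefied table, observed
  richness, rarefaction curves, and the Kruskal–Wallis omnibus test with
  Dunn's post hoc z-tests (Bonferroni-adjusted) between species.
- **Beta diversity** — unweighted and weighted (raw) UniFrac distances,
  principal coordinates analysis (classical scaling of $-\tfrac12 D^2$),
  and PERMANOVA with seeded label permutations, omnibus and per-species-pair.
- **Differential abundance** — ANCOM: for each taxon $i$, all $m-1$
  additive log-ratio tests $\log\frac{c_i + 1}{c_j + 1}$ across species
  (Kruskal–Wallis, Benjamini–Hochberg within the taxon's tests);
  $W_i$ counts rejections and a taxon is flagged when
  $W_i \ge 0.7\,(m-1)$.
- **Interaction networks** (the heart of the package) — per mosquito
  species: drop ASVs below 0.1 % of the species' total reads, collapse
  ASVs to genus by shared lineage, convert to percent relative
  abundance, compute all pairwise Spearman correlations (tie-corrected
  midranks; *exact* permutation p-values for groups of ≤ 8 specimens,
  t-approximation above), and keep edges with $|\rho| > 0.75$ and
  $p < 0.05$.  Positive edges are co-occurrence, negative edges
  co-exclusion; graphs export as GraphML and edge-list TSV.
- **Synthetic data** — a Dirichlet-multinomial community generator with
  a Gaussian-copula latent layer that plants known positive/negative
  taxon associations and species-specific differential taxa, so every
  stage can be validated against ground truth without sequencing data.

## Worked example

Simulate an 8-species, 111-mosquito survey with planted associations,
then run every stage:

```bash
culicinet simulate --out demo/bundle --seed 42 --n-taxa 120
culicinet run-all \
    --counts demo/bundle/counts.tsv --taxonomy demo/bundle/taxonomy.tsv \
    --metadata demo/bundle/metadata.tsv --tree demo/bundle/tree.nwk \
    --out demo/out --seed 42
```

`demo/out/network_summary.tsv` then reads:

```
species           nodes  positive_edges  negative_edges  isolated_taxa
Ae_scapularis     42     35              15              5
Ae_serratus       30     26              4               10
Hg_capricornii    52     52              42              1
Hg_leucocelaenus  22     19              5               19
Ke_cruzii         14     10              5               17
Ps_ferox          24     7               10              32
Sa_conditus       8      4               0               49
Wy_confusa        9      4               1               35
```

The species with only 6–8 specimens carry many more edges than the
30-specimen group: with so few samples a fairly high Spearman value
arises by chance, so their networks are dense and mostly spurious —
exactly the caveat to keep in mind when reading small-n field networks.
The 30-sample group (`Sa_conditus`) instead recovers planted
associations cleanly (`demo/out/networks/Sa_conditus_edges.tsv`):

```
taxon_a                         taxon_b        rho       p             sign
Acidibacter                     Acinetobacter  0.964850  8.680629e-18  positive
Delftia                         Pseudomonas    0.863404  8.201449e-10  positive
Methylobacterium-Methylorubrum  Puia           0.830478  1.361173e-08  positive
Sphingobium                     Sphingomonas   0.930145  1.048966e-13  positive
```

All four are planted pairs (see `demo/bundle/truth.json`).  Alpha
diversity differs strongly between the simulated species
(`alpha_kruskal.tsv`: H = 73.71, p = 2.6e-13; Shannon indices range
0.36–5.20 across samples), and PERMANOVA on both UniFrac variants
rejects community equality (`permanova.tsv`: unweighted pseudo-F = 8.23,
weighted pseudo-F = 86.81, both p = 0.001 at 999 permutations).

The same stages are available individually (`culicinet alpha`, `beta`,
`ancom`, `network`) and as library functions
(`culicinet.per_species_networks`, `culicinet.ancom`, ...).

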