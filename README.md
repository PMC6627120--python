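# milkbiome

Compositional analysis of human-breast-milk (HBM) 16S rRNA bacteriome
count tables, for microbiome researchers working with OTU-by-sample read
counts and per-sample covariates.

Breast-milk samples are low-biomass, so reagent ("kitome") contamination
is a first-order problem, and their communities are compositional: only
relative information survives sequencing. `milkbiome` implements the full
desk-side analysis chain for such data:

- **Spiked-NTC decontamination** — no-template extraction controls spiked
  with DNA of a known taxon (e.g. *M. smegmatis*) sequence the reagent
  background at sample-like depth. Background features are catalogued from
  the spiked NTCs (spike removed, arithmetic mean read count per feature,
  zeros included), and each feature's mean is subtracted from every
  biological sample, floored at zero. Features never seen in an NTC are
  untouched, bounding over-compensation: `x'_ij = max(x_ij − round(m_i), 0)`.
- **Compositional profiling** — relative abundances `p_ij = x_ij / n_j`,
  mean relative abundance (MRA) summaries, per-sample "other" grouping,
  and the core bacteriome (features present in ≥ 80 % of samples).
- **Alpha diversity** — Shannon–Weaver `H = −Σ p_i log p_i`, bias-corrected
  Chao1 `S_obs + F₁(F₁−1)/(2(F₂+1))`, seeded rarefaction without
  replacement, and the strict `< 1000`-read depth filter.
- **Community typing** — Bray–Curtis dissimilarities, complete-linkage
  hierarchical clustering cut at height 0.8, cluster-number selection by
  the Calinski–Harabasz index `CH(k) = [B/(k−1)]/[W/(n−k)]` on PCoA
  coordinates, validated by silhouette widths on the distances.
- **Aitchison geometry** — Bayesian-multiplicative zero replacement,
  centered log-ratio (CLR) transform, Aitchison distances, and
  lambda-scaled log-ratio biplots.
- **Co-occurrence networks** — genus-level Pearson correlations of CLR
  abundances, hard-thresholded at `|r| > 0.28`, signed edges.
- **Inference** — seeded one-factor PERMANOVA
  (`F = [SS_A/(a−1)]/[SS_W/(N−a)]`, permutation p-values), one-way ANOVA
  of alpha diversity, Benjamini–Hochberg FDR, and replicate-reproducibility
  R² between duplicate library preparations.
- **Synthetic cohorts** — a Dirichlet-multinomial generator producing the
  three HBM community types (*Staphylococcus*-dominant, mixed,
  *Streptococcus*-dominant), a shared contamination background, spiked
  NTCs, and duplicate preparations, with full ground truth for
  parameter-recovery testing.

## Worked example

```python
import milkbiome as mb
from milkbiome.synthetic import SPIKE_FEATURE

# a study-like cohort: 3 x 40 samples + 4 spiked NTCs
table, tax, meta, truth = mb.generate_cohort(mb.default_spec(seed=7))

catalog = mb.identify_background(table, SPIKE_FEATURE)
clean = mb.subtract_background(table, catalog)
clean, removed = mb.filter_min_depth(clean, 1000)

genus, _ = mb.collapse_to_rank(clean, tax, "genus")
comp = mb.to_relative(genus.subset_samples(genus.biological_samples))

d = mb.bray_curtis(comp)
model = mb.hierarchical_cluster(d, cut_height=0.8)
model = mb.select_k(d, model, range(2, 9))
labels = mb.cut_into_k(model, model.selected_k)
res = mb.permanova(d, labels, permutations=999, seed=7)
```

This run prints a background catalog of the four contaminant OTUs
(mean NTC reads 180.5, 98.0, 73.5 and 42.5), finds *Streptococcus*
(39.9 % MRA) and *Staphylococcus* (39.6 %) dominant with *Rothia* (4.8 %)
and *Corynebacterium* (3.5 %) next, reports 13 core genera at 80 %
prevalence, selects k = 3 community types (CH = 361.5, mean
silhouette = 0.77), and confirms the types differ in composition
(PERMANOVA pseudo-F = 1372.4, p = 0.001). The selected k and high
silhouette mean the cohort's three seeded community types were recovered
cleanly; the p-value is the smallest attainable with 999 permutations.

The same steps are available from a shell via the `milkbiome` command
(`simulate`, `decontam`, `core`, `alpha`, `rarefy`, `cluster`, `biplot`,
`network`, `permanova`); every subcommand that draws random numbers takes
a mandatory `--seed`.

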