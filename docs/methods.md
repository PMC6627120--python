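# Methods

This note documents the models, defaults and numerical choices behind
`milkbiome`, and what the synthetic experiments do and do not establish
about real breast-milk data.

## Data model

Count tables are OTU × sample matrices of non-negative integer read
counts (features as rows, the classic QIIME orientation). Each sample
carries a role flag: `biological`, `ntc_spiked` (a no-template extraction
control spiked with DNA of a taxon absent from milk, so reagent
contaminants are sequenced at sample-like depth), or `replicate` (a
duplicate library preparation of another sample's extract, with the
partner recorded). Taxonomy is a fixed six-rank lineage
(kingdom … genus) in the `k__…;g__…` dialect; an empty rank is
"unassigned". When collapsing to a rank, features unassigned at that rank
are keyed by their full lineage prefix — two families' unassigned genera
are never merged — and labelled by the most resolved assigned ancestor
(`Enterobacteriaceae;g__`). Collapsing conserves every column total
exactly (integer arithmetic).

## Spiked-NTC decontamination

Background features are those with any positive count in a spiked-NTC
column, the spike taxon excluded. Each background feature's catalogued
value is the arithmetic mean of its counts across *all* spiked NTCs,
zeros included in the denominator. Subtraction removes the half-up-rounded
mean from every biological column, floored at zero (`floor` and
real-valued `none` modes are flags, since the source procedure does not
state a rounding rule); matching is by exact feature ID. Features absent
from every NTC are returned bit-identical — this is the over-compensation
control: the method can only remove reads from taxa demonstrably present
in reagents. When a metadata column identifies sequencing runs, catalogs
can be built per run (the pooled catalog is the default; the source
protocol does not state which was used).

The procedure assumes the contamination level in samples is comparable to
that in NTCs and constant within a run. It corrects expected counts, not
per-sample realizations, so residual noise remains; the recovery
experiment (below) quantifies the net effect.

## Synthetic cohorts

The generator draws, per biological sample in community type c with
genus profile θ_c and concentration parameter λ (default 200):

    composition ~ Dirichlet(λ·θ_c)    (on the profile's support)
    depth       ~ round(median · exp(N(0, σ)))   median 8000, σ = 0.6
    counts      ~ Multinomial(depth, composition)
    + contaminant reads ~ Multinomial(Binomial(depth, f), background)

with contamination fraction f (default 0.05) over a four-genus reagent
background (Ralstonia, Bradyrhizobium, Sphingomonas, Delftia — typical
kit contaminants). Spiked NTCs contain Poisson spike reads (mean 5000)
plus background at expected `f × median depth` reads, and nothing else.
The depth scale mirrors a median-8000-read amplicon run; an option forces
a chosen number of samples below 1000 reads to exercise the depth filter.

The three default community types are Staphylococcus-dominant
(0.75/0.05), mixed (0.40/0.40) and Streptococcus-dominant (0.05/0.75),
with the remaining mass spread over Rothia, Corynebacterium, Veillonella,
Gemella, Acinetobacter, Micrococcus, an unassigned Enterobacteriaceae
genus, and low-level Lactobacillus/Bifidobacterium/Pseudomonas/
Enhydrobacter. The non-dominant member of each dominant pair is kept at
5 %, not 0: both genera are near-universal in breast milk (they are core
taxa), and a structural zero would contradict that ecology. By default
each genus is one OTU; `otus_per_genus` fans genera into several OTUs
with Dirichlet-split weights to exercise OTU-level code paths.
`generate_guild_cohort` instead plants covariance: a latent per-sample
see-saw factor scales an oral guild (Streptococcus, Rothia, Veillonella,
Gemella) against a skin guild (Staphylococcus, Corynebacterium), giving
positive within-guild and negative between-guild correlations.

What the generator does **not** emulate: sequencing error and chimeras,
phylogenetic structure, per-run batch effects, overdispersion beyond
Dirichlet-multinomial, taxon-specific amplification bias, and covariate-
dependent composition shifts. Passing recovery tests therefore shows the
*algorithms* behave as specified under their own assumptions, not that
real cohorts satisfy those assumptions.

## Diversity

Shannon uses the natural log by default (`base` is exposed; ecosystems
disagree and the convention is not recoverable from the source analyses).
Chao1 is the bias-corrected estimator `S_obs + F₁(F₁−1)/(2(F₂+1))`,
defined even when no doubletons exist; the classic `F₁²/(2F₂)` form is a
flag. Rarefaction subsamples without replacement via multivariate
hypergeometric draws (seeded); a depth equal to the sample total
reproduces the exact metric with zero variance, and depths beyond the
total are skipped, never extrapolated. The depth filter removes
biological samples with *strictly* fewer reads than the threshold
(default 1000); controls and replicates are never depth-filtered. Final
diversity metrics are computed on depth-filtered, non-rarefied counts;
rarefaction is diagnostic only.

## Community typing

Bray–Curtis dissimilarities are computed on genus-level relative
abundances. Complete linkage (merge criterion: maximum pairwise
dissimilarity) guarantees monotone merge heights; the tree is cut at
height 0.8 and clusters smaller than `min_size` (default 5) are set aside
with label 0, mirroring the exclusion of minor community types from group
comparisons. Cluster-number selection cuts the same tree at each k in
range and scores Calinski–Harabasz on the full positive-eigenvalue PCoA
embedding of the distance matrix — CH needs coordinates, and the
embedding is the representation that preserves the distance structure
without inventing a feature space — with mean silhouette width computed
directly on the distances as validation. `selected_k` maximizes CH, ties
broken toward smaller k (parsimony). Downstream group labels use the
fixed-height cut by default and the k-cut where a specific k is wanted;
both are reported side by side. PCoA Gower-centers `−d²/2` and
eigendecomposes; Bray–Curtis is non-Euclidean, so negative eigenvalues
occur — they are reported and their axes dropped, and proportions
explained are relative to the positive-eigenvalue total.

## Aitchison geometry

Zero replacement is Bayesian-multiplicative: zero cells of sample j get
`δ_ij = α_i/(n_j + Σα)`, nonzero cells are scaled by one minus the
imputed mass, so columns stay unit-sum and ratios among observed parts
are exact. The default prior strength α = 0.5 per feature (Jeffreys-like)
is exposed; the cited zero-replacement family has several variants and
the source analyses do not pin one down. CLR subtracts the per-sample
mean log; Aitchison distance is the Euclidean norm of CLR differences (a
true metric, unlike Bray–Curtis). The biplot is the SVD of the
column-centered CLR matrix with column-principal scaling (γ = 0) and
lambda-balancing: λ = (Σ‖taxon marker‖²/Σ‖sample marker‖²)^(1/4)
multiplies sample markers and divides taxon markers, equalizing total
spreads without changing inner products.

## Networks

Networks are built at genus level on genera with MRA > 0.5 % (recomputed
within each sample subset when per-cluster networks are built, matching
each cluster's own abundance structure). Correlations are Pearson r on
CLR values — CLR mitigates the spurious negative correlation closure
induces on raw proportions; a raw-proportion mode exists for comparison.
Edges require `|r| > 0.28` and keep their sign. Genera with zero variance
are flagged and excluded from edges.

## Inference

PERMANOVA: `SS_T = (1/N)Σ_{j<k} d²_jk`, `SS_W` the within-group
analogue, pseudo-F from the usual degrees of freedom; p-values are
`(1 + #{F_perm ≥ F_obs})/(B + 1)` over B unrestricted seeded label
permutations (default B = 999), so p ∈ [1/(B+1), 1]. On Euclidean
distances the decomposition equals a centered-coordinate ANOVA, and the
pseudo-F matches scikit-bio's implementation to 1e-9 (both are test
oracles). The implementation is single-factor; covariate scans run one
model per covariate per taxonomy level and BH-adjust the whole family
together, with rows sorted so the significant set is independent of input
order. Alpha-diversity comparisons use one-way ANOVA (for a single factor
this coincides with a Type II test). Replicate reproducibility is the R²
of regressing duplicate OTU counts on their originals.

## Experiment sizes and measured behavior

The simulation studies in `milkbiome.benchmarks` (shared by the test
suite and `scripts/acceptance.py`) use: decontamination — 60-sample
cohorts at contamination fractions 0.01–0.2 with 4 spiked NTCs, 20 seeds;
community typing — 3 × 40-sample cohorts at concentration 200, 20 seeds;
PERMANOVA calibration — 1000 structureless two-group replicates at
B = 199, and power against a 1-pooled-SD mean shift at n = 30 per group,
200 replicates; network sign recovery — 20 guild cohorts of 60 samples at
cutoff 0.28; replicate reproducibility — duplicate multinomial draws at
depth 10⁵. These sizes are the package's chosen study conditions.

The power experiment simulates directly in CLR coordinates. Its
dimensionality matters: a fixed-magnitude shift loses power as pure-noise
axes are added. The default is the CLR image of a 3-part composition
(2 effective coordinates), the smallest non-degenerate compositional
geometry, so the nominal effect size is not diluted; `n_features` is an
argument for studying the dilution.

## Known limitations

- Decontamination subtracts a constant per feature; it cannot adapt to
  per-sample contamination load (e.g. biomass-dependent contamination).
- Multi-factor PERMANOVA (sequential term addition) is not implemented;
  covariates are tested one at a time.
- The 0.8 cut height and CH selection can disagree; both are reported and
  the package takes no position on which is "the" community typing.
- Classic Chao1 is undefined for samples with singletons but no
  doubletons; the bias-corrected default avoids this but differs slightly
  from the classic estimator elsewhere.
- Newick export writes the dendrogram with merge-height branch lengths;
  it is a visualization aid, not a phylogeny.
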