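# Methods

## Statistical models

### Negative-binomial differential expression

Counts are modeled as NB(μ, α) with Var = μ + αμ², log link, per-sample
size factors as offsets. The full model is `~ 1 + condition`, the reduced
model `~ 1`; the test statistic is LR = 2(ℓ_full − ℓ_reduced) referred to
χ²(1), and log2FC is the condition coefficient divided by ln 2. Fitting is
vectorized iteratively reweighted least squares across genes (Fisher
weights w = μ/(1 + αμ), shared design), declared converged when both the
relative log-likelihood change falls below 1e-8 and the coefficient step
below 1e-8, with a 100-iteration cap; non-converged genes are reported with
p = 1. All-zero genes are skipped.

Size factors are median-of-ratios over genes positive in every sample,
rescaled to geometric mean 1. Dispersion is a per-gene method of moments on
normalized counts, α̂ = max(0, (s² − μ̄)/μ̄²) pooled within condition then
averaged, floored at 1e-8. This deliberately omits shrinkage-based
estimators: the downstream logic consumes directions and ranks, not exact
tail probabilities. The cost is mild anti-conservatism at small n — the
measured type-I error at nominal .05 is ≈ 0.06–0.07 for n = 8/8 at
dispersion 0.1 — which the calibration test bounds.

DEG calls use raw p < .05 (BH-adjusted p is reported alongside), matching
the screening role of the per-dataset lists; direction conflicts are
resolved later, at integration.

One exact invariance is asserted rather than an approximate one: rescaling
*all* size factors by a common constant shifts only the intercept and
leaves log2FC and p unchanged. Rescaling a single sample's counts together
with its size factor is not an exact invariance of the NB likelihood
(observation weights depend on absolute counts) and is not asserted.

### Sample QC and balancing

QC computes Pearson correlation on log2(count + 1) between all sample
pairs and iteratively removes the sample with the lowest mean correlation
while that mean is below 0.8 (the transform and coefficient are our
choices; the rule only needs to isolate grossly discordant libraries).
Unequal groups are balanced by seeded subsampling without replacement.

### Differential H3K27ac regions

Consensus peaks merge chains of ≥1-bp-overlapping replicate peaks
(half-open coordinates) and keep merged intervals supported by at least two
replicates. Count-mode differential regions reuse the NB LRT on a
peak-count matrix and call regions at BH FDR < 0.05; presence/absence mode
calls a region gained when a case consensus peak has zero overlap with
every control peak (and vice versa for losses). Replicate jitter in the
generator is capped at 50 bp precisely so the presence/absence overlap
logic is exercised without destroying truth.

Annotation classifies each signed region: promoter if it overlaps any
strand-aware [TSS − 3000, TSS + 3000) window (ties broken by nearest TSS,
then lexicographically smallest gene id, for determinism); otherwise, if it
overlaps no gene body, it is intergenic and inherits all genes of
overlapping enhancers that survived the filter (enhancer score ≥ Q1 of all
enhancer scores, association score ≥ Q1 of all association scores, both by
linear-interpolation quantiles, and at most five surviving genes per
enhancer — enhancers exceeding that are dropped entirely); genic
non-promoter regions are discarded. Acetylation gain maps to direction +1,
loss to −1, treating the mark as activating.

### Integration

Within a condition, every dataset/assay contributes a gene → direction map;
genes observed with both signs anywhere in the condition are excluded as
discordant (one uniform rule for RNA–RNA, RNA–ChIP and ChIP–ChIP
conflicts). Across conditions, common genes split into concordant (same
direction — the genes of interest) and discordant sets; the partition
identity |common| = |concordant| + |discordant| is asserted at run time.

### Enrichment

ORA is the exact hypergeometric upper tail within a stated universe
(default: all genes tested for differential expression), BH-corrected.
GSEA uses the weighted Kolmogorov–Smirnov running sum with weight 1 on the
ranking by mean log2FC across the two conditions; because that ranking is a
derived statistic rather than per-sample data, significance comes from
seeded gene-label permutations, p = (1 + #{|ES*| ≥ |ES|})/(1 + n_perm). The
leading edge is the hit set up to the running-sum extremum (for negative
ES, from the extremum onward). Term clustering uses average linkage on
1 − Jaccard of annotated gene sets, cut to k clusters; Jaccard is our
choice of similarity where none is canonical.

### Signed co-expression networks

The expression input is log2(normalized count + 1) — a documented
approximation of the variance-stabilizing transform; downstream Pearson
correlations are rank-dominated and insensitive to the exact curvature at
low counts. Batch adjustment is empirical-Bayes location/scale correction
(ComBat, via scanpy) on the transformed scale with the case/control
condition protected as a covariate; count-scale batch correction is not
replicated. The condition covariate is passed as a numeric indicator
because a categorical covariate would be dummy-expanded without a reference
level and make the design singular.

Adjacency is the standard signed form a = ((1 + r)/2)^β. The soft threshold
β is the smallest power whose connectivity distribution reaches a signed
scale-free fit R² ≥ 0.8 (log-log regression over 10 equal-width bins),
falling back with a warning to the best-fitting power; configurations may
pin β per condition instead. On the bundled synthetic study the planted
block structure is not scale-free, so the fallback (β = 20) is expected and
harmless — module recovery is driven by the contrast between within- and
between-module overlap, not the absolute exponent. TOM follows the usual
formula TOM_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij).

**Module detection.** The 1 − TOM average-linkage dendrogram is decomposed
top-down rather than cut at a single height: a branch is split while its
two sub-branches' eigengenes (sign-oriented so members point positive)
correlate below 1 − merge_height; a branch whose sub-branches cohere, with
at least min_module_size (30) members and a first principal component
explaining at least min_coherence (0.3) of member variance, becomes a
module; everything else is label 0. A single static cut proved structurally
unable to separate modules from background here: background merges crowd
the top of the dendrogram, so any one height either splinters the
background into spurious size-≥30 branches or absorbs modules into it. The
per-branch criterion uses exactly the machinery the merge step already
defines, signed because anti-correlated branches are unconnected in a
signed network. Detected modules whose eigengene dissimilarity falls below
the 0.25 merge height are then merged iteratively, and labels are
canonicalized (decreasing size, ties by smallest member id) so results are
invariant to gene input order. min_coherence = 0.3 sits well above the
first-PC variance fraction of a pure-noise branch at these sizes
(Marchenko–Pastur scale, ≲ 0.18) and below that of any planted module at
loading ≥ 0.5.

Module eigengenes are unit-norm first right-singular vectors of the
standardized member matrix, sign-fixed so mean member kME > 0; kME is
computed for all genes against all modules. Module–trait correlation is
Pearson r against the 0/1 condition with p from the t-distribution
(n − 2 df).

### Module preservation

Seven statistics evaluate a discovery module in the test network:
avg.weight (mean off-diagonal test adjacency), coherence (mean squared
test kME), avg.cor (mean |test correlation|), avg.contrib (mean |test
kME|), and the concordance statistics cor.cor, cor.degree, cor.contrib
(Pearson correlations of discovery vs test pairwise correlations,
within-module degrees, and kME vectors). avg.cor uses absolute
correlations; eigengene signs follow the member-majority convention so
cor.contrib is sign-stable. Null distributions come from seeded draws of
random same-size gene sets from the shared universe (module genes included
by default; exclusion is a flag), recomputing the test side against the
fixed discovery structure; p = (1 + #{null ≥ obs})/(1 + n_perm), BH jointly
across modules × statistics (per-statistic correction available). A module
is preserved only when all seven adjusted p-values are below 0.05 — the
strictest reading, configurable. Fewer than 20 permutations is rejected as
too coarse.

The concordance statistics carry information only when members have
heterogeneous connectivity; this is why the generator draws per-gene
loading multipliers (below).

### Hub genes

Within preserved, trait-correlated modules, kIM_i = Σ_{j∈module} a_ij
(excluding self). Hubs satisfy both kIM ≥ the module's 90th percentile and
kME > 0.8; the top five by kIM (ties by kME, then gene id) form the
headline list.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
the biology of any particular dataset:

- **Counts**: log μ = baseline + batch + DE shift + Σ loading × factor;
  counts ~ NB(μ, α) with a single α (default 0.1). Baselines are
  U(3, 8) on the natural-log scale (means ≈ 20–3000), batch offsets are
  gene-wise Gaussian per dataset (SD 0.5) — the minimal structure the batch
  adjustment must remove.
- **Modules**: one latent factor per module per sample; members load with
  module loading × a per-gene multiplier U(0.5, 1), giving the
  heterogeneous connectivity real modules have (and that cor.degree /
  cor.contrib and the hub definitions require). Shared modules receive a
  factor in both conditions; condition-specific modules only in their own.
  A module's condition association is a mean shift of its factor in case
  samples (`trait_shift`), which makes members differentially expressed
  with log2FC = loading × shift / ln 2 and the module eigengene
  trait-correlated — while keeping each module a single correlation block.
  (Planting independent per-gene DE shifts inside modules instead creates
  nested DE/non-DE sub-blocks that detection then faithfully splits.)
- **Standalone DE genes** get per-gene log2FC = ±2; some are planted with
  opposite signs across conditions to populate the discordant bin.
- **Annotation**: non-overlapping gene bodies (2–8 kb) on synthetic
  chromosomes, ~500 genes each, strand random, TSS at the strand-aware
  body end; enhancers (0.4–1.2 kb) strictly intergenic and ≥ 3.1 kb from
  every TSS so planted enhancer peaks are never reclassified as promoter
  peaks; 1–8 nearest-gene associations with uniform scores.
- **Peaks**: background promoter peaks present in both groups; planted
  gains only in case replicates, losses only in control; ≤ 50 bp replicate
  jitter. For count-mode conditions, NB read counts under the consensus
  peaks carry 4-fold planted shifts.
- **Gene sets**: one term per planted module, DE up/down terms per
  condition, plus random terms — enough structure for ORA/GSEA to find and
  for null calibration.

Everything is a pure function of the seed (independent substreams per
purpose via SHA-256 of `(seed, tag)`), so all outputs are byte-reproducible.

The bundled study (`default_config`) fixes the conditions used throughout
the tests: 2 conditions × 2 datasets, 2000 genes, 10 samples per group
(40 per condition), five modules of sizes 200/150/120/80/50 at loading 0.8
(three shared, two exposure-specific), factor shifts giving |member
log2FC| = 2 at the module loading, 170 standalone DE genes (40 up + 40
down shared, 30 discordant, 60 condition-specific), ~50 planted peak
gains/losses per condition across promoters and enhancers, and 200
preservation permutations. Module recovery is scored by adjusted Rand
index on the genes belonging to planted modules: background genes carry no
planted module constraint, and condition-responsive background genes
legitimately co-express (through the shared case/control axis), so their
clustering is genuine generator structure rather than detection error.

What passing these tests does *not* show about real data: the generator's
modules are exact single-factor blocks, its noise is homoscedastic NB with
one dispersion, batch effects are purely additive on the log scale, and
peak geometry is idealized. Real datasets add dispersion trends, correlated
batch × condition structure, and annotation ambiguity that this pipeline
inherits from its inputs rather than resolves.

## Pipeline and reproducibility

The pipeline is file-based: each stage reads from and writes to a
workspace directory (TSV/BED/GMT/JSON), so stages can be re-run in
isolation and two runs with identical config and seed produce
byte-identical outputs (asserted in the test suite). A global seed fans out
to per-stage seeds via a stable hash. Result tables carry the config hash
(computed over the configuration minus the output path) in a header
comment. The per-condition network universe is the union of all DEGs and
GADER genes surviving the low-count filter, shared by both networks so
condition-specific structure can be tested for (non-)preservation. Problem
sizes in the bundled study (2000 genes, 200 permutations, 3 seeds for the
recovery checks) were chosen so the full suite and the acceptance script
each complete in a few minutes on one CPU while keeping every planted
effect comfortably detectable.

## Known limitations

- Dispersion has no shrinkage; small-sample p-values are mildly
  anti-conservative (bounded by the calibration test).
- The VST is a log transform, not the closed-form dispersion-trend VST.
- Batch correction operates on the transformed scale, not on counts.
- Scale-free fit selection is meaningful only for data that are plausibly
  scale-free; block designs trigger the documented fallback.
- Preservation null draws include the module's own genes by default
  (simple null); exclusion is available but changes p-values only
  marginally when the universe is much larger than the module.
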