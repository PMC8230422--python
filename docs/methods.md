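# Methods

This note documents the models, numerical choices and limitations of each
pipeline stage, and what the synthetic generators do and do not emulate.

## Expression containers and identifier handling

All stages operate on a gene-by-sample matrix (log2 intensities/abundances)
with per-sample annotations; counts are a subtype carrying library sizes,
TMM factors and optional gene lengths (kb). Gene identifiers are matched by
exact, case-sensitive string comparison throughout — alias or ortholog
resolution is curation work outside the package's scope. Duplicate feature
rows must be collapsed explicitly (MaxMean: per gene, keep the feature with
the highest mean across samples; ties go to the lexicographically smaller
feature identifier, making the result order-independent).

## Normalization

**TMM.** For sample k against reference r, using only genes with positive
counts in both libraries: M_g = log2[(y_gk/N_k)/(y_gr/N_r)],
A_g = ½·log2[(y_gk/N_k)(y_gr/N_r)], weights w_g equal to the inverse
delta-method variance (N_k−y_gk)/(N_k y_gk) + (N_r−y_gr)/(N_r y_gr). Genes in
the upper/lower 30% of M and 5% of A are trimmed (both trims must pass); the
factor is 2 to the weighted mean of the surviving M values. The reference
defaults to the sample whose upper-quartile count fraction is closest to the
panel mean; factors are rescaled to geometric mean 1 (asserted to 1e-12 in
tests). Identical count proportions short-circuit to factor 1. These defaults
are the method's canonical ones; trims and reference are parameters.

**CPM / FPKM.** CPM divides by the TMM-effective library size (N_k·f_k); in
log mode a prior count of 0.5 is added to counts and 1.0 to the effective
library size before log2 (the voom-style transform; both constants are
parameters). FPKM divides by gene length in kb times N_k/1e6 and is provided
for single-sample scoring workflows; it deliberately does not use TMM
factors.

**Quantile normalization.** Every sample's sorted vector is replaced by the
across-sample mean of order statistics. Tied values within a sample receive
the mean of the reference values their block spans — deterministic and
rank-preserving, and the transform is idempotent.

**z-scoring and merging.** Gene-wise standardization uses the sample (n−1)
standard deviation; this convention is fixed and tested ([1,2,3] → [−1,0,1]).
Zero-variance genes become 0 with a logged count. Merging intersects gene
spaces (datasets profiled on different platforms share only part of the
genome; union-with-missingness would poison rank-based scoring downstream),
z-scores within each dataset, concatenates, and quantile-normalizes the
result. Additive per-(gene,dataset) shifts — the batch model of the
generator — are removed exactly by construction; multiplicative or
nonlinear batch effects are only partially absorbed.

## Moderated differential expression

Per gene, a (optionally precision-weighted) group-means least-squares fit
yields residual variance s²_g on d degrees of freedom. The prior (d₀, s₀²) is
estimated by moment matching on z_g = log s²_g: with
e_g = z_g − ψ(d/2) + log(d/2), the excess variance
var(e) − ψ′(d/2) determines d₀ through the inverse trigamma (Newton
iteration); s₀² follows from the mean of e. An infinite d₀ estimate is
truncated to 10× the median residual df so the posterior remains a proper
mixture; an explicit user-supplied prior df is honored untruncated (0
recovers the ordinary t exactly; ∞ collapses all variances to s₀²). The
moderated t uses s̃² = (d₀s₀² + d·s²)/(d₀+d) on d₀+d df; the ANOVA F uses the
same posterior variance. Zero-residual-variance fits (noiseless synthetic
data) produce ±∞ statistics with p ∈ {0, 1}, which keeps the noiseless
planted-truth checks exact. Fold changes are reported as signed log2
differences of class means; user-facing thresholds are linear fold changes,
converted internally.

voom-style weights: residual sqrt-standard-deviations are lowess-smoothed
(span 0.5) against average log2 count; each observation's weight is the
inverse fourth power of the trend at its fitted log2 count, with constant
extrapolation beyond the fitted range and a positive floor. At least 10 genes
are required — a trend cannot be fit on fewer.

**Signature rule.** A gene is target-tumor-specific when its fold change is
at least `fc_threshold` (default 2) versus both the other tumor class and
normal tissue, below `other_fc_threshold` (default 1.5, signed) in the
other-tumor-versus-normal contrast, and the overall ANOVA FDR is below 0.25.
The 0.25 discovery gate and the stricter 0.05 replication gate are both
parameters because small rare-tumor cohorts cannot support 0.05 at discovery.
The rule is monotone in all thresholds (tested).

**Consensus cores.** A gene enters the up (down) core when it passes
|FC| ≥ 2, FDR < 0.05 with a consistent sign in ≥ 3 of the supplied per-dataset
results; both cutoffs and the dataset count are parameters.

**Single-cell markers.** Two-sided Wilcoxon rank-sum (normal approximation,
tie and continuity correction) of the target type against all other cells;
genes constant across all cells get p = 1 by definition.

## Single-sample scoring

With n measured genes, ranks ascending and averaged over ties, and m
signature genes present in the matrix, the score is the mean signature rank
divided by n, normalized by its attainable range [(m+1)/2n, (2n−m+1)/2n] and
centered: up-only ∈ [−0.5, 0.5]. A down-set is scored on descending ranks;
the bidirectional total is the exact sum of the two parts, in [−1, 1].
Signature genes missing from a matrix are dropped (m adjusts) rather than
imputed — the cross-platform use case is precisely that gene spaces differ.
Up-only is the default mode for signatures defined as upregulated gene lists;
bidirectional is available when a down component exists.

The per-cell recovery AUC ranks genes by expression descending (ties by
average rank; the cut between tied genes is by identifier order — a
deterministic choice in place of the randomized tie-breaking of common
implementations; reproducibility wins, and the effect vanishes for
non-degenerate data) and integrates the hit count over the top
T = ceil(0.05·n) positions, normalized by its maximum Σ min(k, m). The 0.05
top fraction is the method's customary default and a parameter. Empirical
significance uses uniformly random gene sets of the signature's size (default
1000), retained per cell.

## Enrichment

ORA is the upper-tail hypergeometric P(X ≥ k) per term, with terms
intersected with the user-supplied universe and BH across terms.

Preranked GSEA sorts genes by statistic (ties broken by identifier), runs the
weighted KS sum — hits add |r|^p/Σ_set|r|^p (p = 1), misses subtract
1/(n−m) — and takes the signed maximum excursion; extrema are evaluated only
immediately before/after hits, which is exact, and an exact tie between the
positive and negative excursion resolves to the positive one. Because only a
ranked list exists, the null permutes gene-set membership (random same-size
sets), not phenotypes. NES divides ES by the mean |null ES| of matching sign;
p and FDR come from the sign-matched null pools (pooled across sets for the
FDR, per the original two-pool scheme). Default set-size window 15–500 after
intersection. The ES implementation is cross-checked in tests against an
independent external implementation and against literal running-sum
enumeration.

Term networks: Cohen's kappa over binary gene-membership vectors of each term
pair, with the universe defaulting to the union of the supplied terms' genes
(the external tool this mirrors does not restate its universe; it is a
parameter). κ = 1 when chance agreement is 1. Edges at κ ≥ threshold (0.5 and
0.35 are both in common use; the threshold is never hard-coded), communities
by greedy modularity maximization with deterministic node ordering — a
reproducible stand-in for force-directed visualization clustering; the tested
property is planted-structure recovery, not exact cluster identity.

## Cell of origin

Bulk profiles are z-scored per gene across bulk samples (absorbing per-sample
affine effects); single-cell values are used as provided — the asymmetry is
intentional, matching how log-normalized references are distributed. Pearson
correlation is computed over the top 5000 most-variable single-cell genes
(variance pooled over all cells, ties by identifier) intersected with the
bulk gene space; fewer than 3 informative genes makes a correlation undefined
(excluded from medians); zero-variance cells are excluded with logged counts.
Each (sample, type) cell is the median r over that type's cells; the
per-sample argmax is the assigned origin, ties broken by type name and
flagged. This is a similarity ranking, not a deconvolution — mixtures of
types are not modeled.

## Drug screen

Spearman correlation between the per-line signature score and each compound's
AUC, pairwise-complete per compound; compounds observed in fewer than 20
shared lines (parameter) are skipped and reported. The p-value uses the
t-approximation with tie-corrected ρ; an exact permutation option exists for
very small panels (n < 12). BH across tested compounds; active means ρ < 0 at
FDR < 0.05 (lower AUC = more sensitive), inactive means ρ > 0 — the labels
partition by construction. Cross-panel concordance matches compounds by exact
lowercase name (or an explicit map), intersects active calls and correlates
the two ρ profiles. Target modulation reports up/down/ns per (compound,
target) from a tumor-versus-normal DE table, flagging absent targets as
missing rather than silently non-significant.

## Consensus subtyping

The grid is (top 1000–5000 variable genes, step 1000) × (sd, MAD, CV, ATC) ×
(Ward, k-means with 25 seeded restarts, PAM) for k = 2..4. CV uses
sd/(mean + s₀) with s₀ the 10th percentile of gene means, guarding
near-zero denominators; ATC ("ability to correlate") is the mean absolute
Pearson correlation of a gene to the others (the area above the sorted-|r|
curve), against an evenly spaced gene subsample above 1000 genes for cost.
PAM is a compact deterministic BUILD + greedy-SWAP implementation. The
consensus entry (i,j) at each k is the fraction of grid combinations
co-clustering i and j — joint co-classification across all combinations, not
per-combination voting. The reported partition cuts the average-linkage tree
of (1 − consensus); k maximizes the mean silhouette on those distances, ties
to the smaller k (a small-cohort prior favoring coarse, stable splits). The
proportion of ambiguous pairs (consensus in (0.1, 0.9)) is reported as a
stability diagnostic. The three omitted base algorithms of larger consensus
frameworks (spherical k-means, model-based, NMF) add nothing to the tested
property — recovery of planted separation — and the algorithm grid is
pluggable.

Subtype markers: per subtype, a subtype-versus-rest moderated fit; the top
150 genes by moderated t among positive fold changes (count and threshold are
parameters; a warning fires when fewer positives exist).

Subtype correspondence is an explicit simplification of two-cohort mapping
algorithms: score cohort B with each A-subtype marker set (single-sample
score), take the mean score difference of each B subtype versus the rest,
build the null by shuffling B labels (default 1000 permutations, one-sided
add-one p), and Bonferroni-adjust over all tested pairs — the output form
(an adjusted p matrix over subtype pairs) matches the established tools while
avoiding their GSEA-based inner loop.

## Synthetic generators

The generators define the study conditions for every test; all are fully
seed-determined.

* **Bulk compendium** — gene baselines N(7, 1.5) on log2; disjoint planted
  classes (tumorA-specific up, shared up, optional down in both tumors, log2
  effect 2 by default); additive per-(gene,dataset) batch shifts N(0, 0.5²);
  residual noise N(0, 0.5²). Four datasets of 10 samples per class mirror a
  realistic multi-cohort rare-tumor setting. Count mode exponentiates the
  log2 means into gamma-Poisson (negative binomial) counts with dispersion
  phi (variance mu + phi·mu²). The batch model is additive by design — the
  exact effect that per-dataset z-scoring removes; confounded or nonlinear
  batch structure is out of scope.
* **Single cell** — baselines Uniform(0.5, 2) in log-normalized-style units,
  disjoint marker sets (+2 log2 in their type), Gaussian noise (sd 0.5),
  clipping at 0, then independent Bernoulli dropout (rate 0.3). Dropout is
  independent of expression level, which stresses rank-based scoring without
  fitting a zero-inflation model; UMI counting noise and ambient RNA are not
  modeled.
* **Cell-line panel** — latent signature activity per line ~ N(0,1); the
  signature genes' expression shifts by 1·activity; active compounds' AUC =
  0.5 + slope·activity + N(0, 0.05²) with slope −0.5, clipped to [0,1]
  (clipping only creates ties at the extremes; Spearman screening is
  unaffected); inert compounds are independent of activity. An optional
  separate activity seed lets two panels share the planted compound truth,
  emulating two pharmacogenomic resources assaying the same drugs.

Passing the planted-truth tests therefore shows that each method recovers the
structure it targets under Gaussian/NB noise, additive batch effects and
independent dropout — not that it is robust to annotation errors, confounded
designs, or platform-specific artifacts absent from the simulations.

## Problem sizes and numerics

Test and acceptance runs use 2000-gene compendia (30 samples per dataset),
300-cell single-cell matrices, 200-line × 100-compound panels, 500-set
enrichment calibrations with 200 permutations, 500-replicate BH and
200-replicate screen nulls, and a reduced consensus grid (top 100/200 genes)
on 20 samples — sizes chosen so the full pipeline, including calibration
loops, completes in well under a minute per stage on one CPU while leaving
the Monte-Carlo standard errors small relative to the asserted margins.
Add-one permutation p-values ((1+b)/(1+B)) are used everywhere, making them
slightly conservative but never zero. Known limitations collected from the
sections above: no covariate or random-effect designs, no count-based exact
tests, no deconvolution, no survival modeling, and no web-service annotation
retrieval — gene-set collections are supplied as GMT files.
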