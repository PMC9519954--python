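# Methods

This note records the statistical models, parameter choices and numerical
conventions behind `gliastate`, and what the synthetic-data validation does
and does not establish about real data.

## Count model and differential expression

Counts are modelled as negative binomial with `var = μ + φμ²` and a single
dispersion φ shared across genes (the "common dispersion"). The classic
exact-test route is used throughout, because it is fully specifiable and
testable against exhaustive enumeration:

1. **TMM factors.** Each sample is compared to a reference sample (the one
   whose upper-quartile expression, scaled by library size, is closest to
   the mean upper quartile). Per-gene log2 ratios M and average log2
   abundances A are formed from library-size-scaled counts; genes with a
   zero in either sample drop out. The most extreme 30 % of M on each side
   and 5 % of A on each side are trimmed (rank-based, average ranks for
   ties) and the factor is the precision-weighted mean of the remaining M,
   with weights equal to the inverse delta-method variance
   `(N−y)/(Ny)` summed over the two samples. Factors are rescaled to
   geometric mean 1. Depth invariance is exact for a pure depth change
   (all M = 0 → factor 1) and holds to ~0.5 % for general data, because
   the precision weights depend on absolute counts.
2. **Library equalization.** Observed counts are mapped to "pseudo-counts"
   at the geometric-mean effective library size by NB quantile matching
   (averaging normal and gamma tail approximations, with the tail chosen
   per observation for accuracy). Dispersion estimation equalizes within
   condition groups (group means may differ); the exact test equalizes
   under the null (one common proportion per gene).
3. **Common dispersion.** φ maximizes the NB conditional log-likelihood of
   the pseudo-counts given per-group totals, optimized over
   `delta = φ/(1+φ)` in `[1e-4, 100/101]`; the equalize/optimize pair is
   iterated twice from a starting φ of 0.01, and the result is clipped to
   `[0, 10]`. Singleton groups contribute nothing (their conditional
   likelihood is constant), so at least one condition needs ≥ 2 replicates;
   otherwise the user must supply φ.
4. **Exact test.** The sum of n i.i.d. NB(μ, φ) counts is NB with size
   n/φ, so conditional on a gene's total s the null distribution of the
   reference-group sum a has weights
   `Γ(a+r₁)/Γ(a+1) · Γ(s−a+r₂)/Γ(s−a+1)` with `rⱼ = nⱼ/φ` (the success
   probability cancels; φ = 0 reduces to the conditional binomial). The
   two-sided p-value sums the probabilities of all outcomes with
   probability ≤ the observed one — not the doubled one-tail, a convention
   that differs in ties — with a relative tie tolerance of 1e-9, capped at
   1. Group sums of pseudo-counts are rounded to integers before
   enumeration. Gamma-function lookup tables make the cost linear in the
   per-gene total.
5. **M and A.** M = log2 of the ratio of equalized condition means with a
   prior count of 0.5 per group (keeps M finite at zeros); A is the
   average log2 CPM on the same prior. FPKM uses the raw column sum as
   library size (no TMM) — the direct spreadsheet-style calculation —
   while CPM accepts TMM-effective library sizes, with the log2 variant's
   prior scaled per sample so all-zero genes map to a constant.
6. **FDR.** Benjamini–Hochberg step-up, DEGs called at strict
   `FDR < cutoff` (default 0.01).

QC for single-nuclei matrices runs in a fixed order — mitochondrial genes
(symbol prefix, default `mt-`, case-insensitive) removed first, then genes
detected in fewer than 200 cells, then cells with fewer than 333 detected
genes — in a single pass, so cell filtering sees the post-gene-filter
matrix but gene detection counts are taken on all cells.

## State-change geometry

Cosine similarity is computed on the intersection of the two vectors'
genes, sorted by gene ID, and reported raw in [−1, 1]; display conventions
that fold it onto 0–1 are left to the caller, and the stored value is
never clipped. By default vectors carry significance-free M values for all
genes (so the gene universe does not depend on power); masking to
`FDR < cutoff` and an FPKM-space variant (log2 ratio of mean FPKM with a
prior of 1) are explicit options, since either space can be meaningful
depending on whether the question is about regulation or absolute
expression levels. PCA is a column-centered SVD with a deterministic sign
convention (largest-|loading| entry positive per component); distances are
Euclidean norms of score differences over the retained components. The
top-k "most differently regulated" genes are ranked by population variance
of M across condition vectors, ties broken by gene ID. Congruence labels
use a default threshold of |M| > 1 (2-fold) in both vectors; the threshold
is configurable because any cut here is a convention.

## Panel curation

Gene symbols are whitespace-trimmed and case-folded before any matching;
alias mapping across nomenclatures is out of scope, so lists from
heterogeneous sources should be pre-harmonized. The enrichment threshold
`log2FC > 2` is strict (boundary genes excluded). Vote counting is
set-based per list, so duplicates within one list count once; raising the
vote threshold can only shrink a panel, and list order is irrelevant (both
are property-tested).

## Synthetic data: what it emulates

The generator produces NB counts with mean
`library_size/1e6 · 2^(baseline + effect)`:

* **baseline** per gene, drawn log-uniform over 2⁰–2¹² by default — a
  realistic bulk dynamic range;
* **dispersion** φ = 0.05 by default (BCV ≈ 0.22, typical for bulk tissue
  replicates); validation runs that emulate deep, near-isogenic culture
  replicates use φ = 0.01 (BCV 0.1);
* **library sizes** default 1e6 (scaled-down from real depths so test
  matrices stay small; all statistics of interest depend on counts per
  gene, which the baseline range controls directly);
* **effects** planted per panel and condition, recorded exactly in a truth
  table. Test fixtures plant balanced up- and down-regulated programs,
  as real differentiation data are roughly composition-balanced; a purely
  one-sided planted program leaves a small residual composition bias
  (~0.01–0.1 log2 units depending on the DE fraction) that TMM trimming
  cannot fully remove — a property of TMM itself, not of the simulator.

For convergence experiments, two orthonormal directions u, w over the
panel genes define planted state changes `m₁u` and
`m₂(cosθ·u + sinθ·w)`, so the true panel cosine is exactly cos θ.
Off-panel genes receive independent N(0, 0.1²) log2 effects so panels
dominate the geometry. The validation setting uses 2000 panel genes,
magnitudes m = 60 (per-gene effects ~1.3 log2 units), 4
replicates/condition, libraries of 2e6 and φ = 0.01: a first-order error
analysis gives an expected attenuation of the estimated cosine of ~1 %
(estimation noise enters both norms), i.e. an expected estimate of ~0.836
for a planted 0.843, well inside the ±0.05 recovery band. Randomness is
split into named sub-streams (baseline, counts, off-panel effects,
directions, voting, image) derived from one seed via spawn keys, so adding
one output does not perturb another.

What passing these tests shows: the pipeline recovers planted fold-changes,
angles and geometry under the NB model with a common dispersion. What they
do not show: robustness to tagwise dispersion heterogeneity, batch effects,
ambient contamination, UMI chemistry, or gene-length biases — none of
which the generator simulates (read-level simulation is a non-goal).

## Image quantification

Distances use pixel-center coordinates; annuli are half-open
`[r, r + bin_width)`. Empty annuli are recorded as missing (NaN) and
linearly bridged (and logged) when integrating; AUC is the trapezoid rule
over bin centers. No background subtraction is applied by default,
matching quantification on raw intensities; lesion "center" is a caller
choice. Colocalization keeps `min(a, b)` where both channels exceed their
thresholds (default 0, i.e. any positive signal); the summary fraction is
relative to reference-channel-positive pixels and defined as 0 when there
are none. The lesion phantom's border-recovery test uses noise at 10 % of
the border/background contrast; at that level the profile peak stays
within one bin of the planted annulus.

## Numerical conventions and degenerate inputs

* Strict inequalities throughout (`M > 2`, `FDR < 0.01`, `< 200 cells`,
  `< 333 genes`), matching the stated rules; boundary cases are tested.
* Cosine similarity and Pearson correlation raise on zero-norm or
  constant inputs rather than returning NaN.
* All-zero samples are rejected by TMM; designs whose NB means would
  overflow are rejected by the generator.
* DEG tables serialize with the fixed column order
  `gene, logFC, logCPM, PValue, FDR`; '.' decimals everywhere.
* Pipeline runs write a manifest with SHA-256 checksums of inputs and
  outputs; identical config + inputs give identical output checksums.

## Known limitations

Common dispersion only (no tagwise/quasi-likelihood route); no batch
correction; exact-test cost grows linearly with per-gene totals (very deep
libraries are better served by the significance-free M route when only
geometry is needed); panel matching is exact-symbol only; single-cell
clustering itself (UMAP/Louvain) is out of scope — only the stated QC
filters and composition summaries are implemented.
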