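# Methods

This document specifies the statistical model, the numerical choices made in
implementing it, the synthetic-cohort generator, and the known limitations.
Notation: `g` indexes exons, `s` samples; `y_gs` is the fragment count of
exon `g` in sample `s`; `L_s` is the library size (total assigned fragments)
and `f_s` the TMM normalization factor.

## 1. Input and counting

Exon catalogs are read from GTF (1-based inclusive coordinates, converted to
0-based half-open internally) or BED.  Duplicate exon identifiers get an
ordinal suffix so every row of the count matrix is uniquely addressable.

Per-exon counting from SAM/BAM uses **union semantics**: a fragment is
assigned to an exon only if every aligned block of the fragment overlaps
exons of exactly one exon id; fragments touching two or more exon ids are
counted as *ambiguous* and discarded.  Paired reads are matched by query
name and counted once per fragment.  Reads that are unmapped, secondary,
supplementary, duplicate, or below the mapping-quality threshold (default
10) are skipped.  Interval lookups use an interval tree per chromosome.

## 2. Preprocessing

1. **Sex-exon removal.**  Exons on chrX/chrY (chromosome names matched
   case-insensitively, with or without the `chr` prefix) are removed before
   anything else, and library sizes are recomputed, because presence on the
   sex chromosomes reflects patient sex rather than disease.
2. **Low-presence filter.**  The literal rule is: remove exon `g` if
   CPM`_gs` < `min_cpm` in at least `min_samples` samples (defaults 1 and
   20).  The more common keep-if-expressed convention ("keep if CPM ≥ c in
   at least k samples") is available behind the `convention` switch of
   `FilterConfig`.  Library sizes are *not* recomputed after this filter, so
   CPM values keep their original meaning.
3. **TMM normalization**, implemented from scratch.  For each sample against
   the reference sample (the one whose upper quartile of CPM is closest to
   the mean upper quartile): exons with zero counts in either sample are
   dropped; the log-ratios `M` are trimmed at 30% on each side and the
   log-abundances `A` at 5%; the factor is the weighted mean of surviving
   `M` values with inverse approximate-variance (delta-method binomial)
   weights; factors are rescaled so their geometric mean is 1.

Log-CPM with prior count `p` (default 0.5) is
`log2((y + p) / (L f + 2p) * 1e6)`.

## 3. The NB GLM

Each comparison uses the design `log mu = beta_0 + beta_1 * 1[group = A]`
with offset `log(L_s f_s)`, where `A` is the first-named group of the
comparison (so a positive reported logFC always means "more present in the
first-named group").  `C_vs_H` assigns both `M` and `N` samples to `C`.
`U` samples are excluded from every design.

Fitting is iteratively reweighted least squares, vectorized across all exons
at once: the per-exon normal equations `X'WX` are formed with an `einsum`
over a (exons × samples) weight array, with a `1e-10` ridge on the diagonal
for safety, linear predictors clipped to ±30, convergence at relative
deviance change < 1e-8 or 50 iterations.  All-zero exons are fitted with
zero deviance by convention.  The unit NB deviance uses the `log1p`
formulation and switches to the Poisson limit for dispersion < 1e-10.

## 4. Dispersion estimation

All dispersion estimation maximizes the **Cox–Reid adjusted profile
likelihood** APL(φ) = ℓ(φ; β̂(φ)) − ½ log det(X'WX), the standard
restricted-likelihood correction for estimating β and φ from the same data.
Dispersions are constrained to [1e-4, 4].

- **Common:** maximize the summed APL over all exons (coarse geometric grid,
  then golden-section refinement).
- **Trended:** exons are sorted by average log-CPM into bins of ~100, the
  common estimator is applied per bin, and the per-bin log-dispersions are
  smoothed by lowess (span 0.5) and interpolated back to each exon.
- **Tagwise:** per exon, maximize APL(φ) − (prior_df / 2) · (log φ −
  log φ_trend)², a quadratic shrinkage penalty toward the trend on the log
  scale; the maximizer is found on a 25-point geometric grid spanning
  trend × 2^±6 followed by parabolic refinement.  As prior_df → ∞ the
  tagwise values collapse to the trend exactly (this is tested).  The
  quadratic-penalty form replaces the weighted-likelihood empirical Bayes
  formulation used by some packages; both shrink log-dispersions toward the
  trend with strength controlled by a prior-df parameter.

Estimation requires residual degrees of freedom ≥ 2.

## 5. Differential tests and the consensus call

- **LRT:** refit under the null (intercept-only) design with *tagwise*
  dispersions; the statistic is the deviance difference, referred to
  χ²(1 df).
- **QLF:** fit with *trended* dispersions; the raw quasi-dispersion is
  `s²_g = deviance_g / df_residual`.  The `s²_g` are moderated by an
  empirical-Bayes squeeze onto an abundance trend: the prior df is obtained
  by moment-matching a scaled F distribution via a trigamma-inverse Newton
  solve, the trend by lowess of `log s²` on average log-CPM with digamma
  bias correction.  The statistic `(deviance difference) / s²_squeezed` is
  referred to F(1, df_residual + prior_df), or to χ²(1) when the prior df
  is infinite.
- **Multiplicity:** Benjamini–Hochberg step-up, implemented directly as the
  running minimum of `p_(i) · m / i` over suffixes.
- **Consensus:** an exon is called DPE at threshold τ iff *both* FDRs are
  ≤ τ.  The intersection can only remove false positives relative to either
  single list, so the consensus empirical FDR is at most that of either
  test (asserted in the pipeline and verified against simulation truth in
  the tests).  Direction is the sign of the reported logFC.
- **Reported logFC:** coefficients are refit once with a +0.125 prior count
  added to every cell (damping infinite fold changes from zero groups);
  these shrunken coefficients are reported but *not* used for testing.

The **exonic signature** is the set intersection of the consensus sets of
the comparisons that could be run, together with counts of every exclusive
Venn region.

## 6. Exploration

- **Hierarchical clustering:** Ward linkage (Ward.D2 criterion, via SciPy)
  on Euclidean distances between sample columns of the signature log-CPM
  matrix; only non-`U` samples are clustered.
- **PCA:** SVD of the column-centered sample × exon matrix.  Component signs
  follow a deterministic convention (the loading of largest magnitude is
  made positive) so output is reproducible.  `U` samples are *projected*
  onto the fitted axes using the training means and loadings; they never
  influence the fit, and output tables carry an explicit `projected` flag.
- **MDS:** the distance between two samples is the root-mean-square of the
  `top_k` largest absolute log-CPM differences ("leading log-fold-change"
  distance), embedded by classical Torgerson MDS (double-centering +
  eigendecomposition, deterministic signs).

## 7. Classification

A random forest (scikit-learn) with all features considered at every split
(`max_features=None`, the analogue of mtry = number of variables), default
5,000 trees.  Evaluation is by repeated stratified 70/30 train/test splits
(default 10 repeats); the report carries mean ± sd of out-of-bag error on
the training block and accuracy on the test block, plus per-class
sensitivity.  `U` samples are assigned to the class with the highest mean
predicted probability across repeats; if the top two mean probabilities are
within 0.05 the assignment is flagged as a near-tie.

Note an intrinsic property of the triple-intersection signature: it is
dominated by metastasis-specific exons, on which `N` and `H` profiles are
identical, so three-class accuracy depends on whether any cancer-wide exon
survives the intersection.  The classifier reports per-class sensitivity so
this is visible rather than hidden in a single number.

## 8. Over-representation

For each gene set, the overlap `k` between the signature genes and the set
(both intersected with the universe of all genes in the catalog that
survived filtering) is tested with the upper-tail hypergeometric
probability `P(K ≥ k)`, identical to one-sided Fisher's exact (verified
against `scipy.stats.fisher_exact` in the tests), with BH adjustment across
sets.

## 9. The synthetic-cohort generator

Counts are NB with mean `cpm_gs / 1e6 · L_s` and dispersion
`φ_g = 2/μ̄_g + 0.1`, the usual decreasing mean-dispersion trend.  Baseline
abundances are log2-CPM ~ Normal(4, 2) truncated at 0; library sizes are
log-normal around 3 × 10⁷ fragments (sd 0.3 on the log scale), emulating a
shallow whole-exome cfDNA assay.  Two differential mechanisms:

- **metastasis-specific** exons shift the `M` mean by ±logfc (log2),
  making them differential in `M_vs_N` and `M_vs_H`;
- **cancer-wide** exons shift both `M` and `N` relative to `H` (generated
  only when healthy samples exist), differential in `C_vs_H` and `M_vs_H`.

True log-fold-changes are recorded exactly from the group offsets; the
`C_vs_H` truth for a metastasis-specific exon is the mixture value
`log2((n_M 2^δ_M + n_N 2^δ_N)/(n_M + n_N)) − δ_H`.  `U` samples draw each
exon's mean from the `M` or `N` value with a fair coin, per exon, placing
them between the groups.  A configurable fraction of exons sits on
chrX/chrY with male/female asymmetry (chrX ×2 in females, chrY ×0.01), so
the sex filter has real work to do.  The default cohort is 17 M / 68 N /
63 H / 11 U.

Realism and limits: the generator reproduces the count-level properties the
statistics are sensitive to (NB noise with a mean-dispersion trend, library
size variation, compositional effects through TMM, nuisance sex signal,
between-group mixtures) but not fragmentomic detail (fragment-length
distributions, GC bias, mappability, batch effects) — none of which the
downstream model consumes.

## 10. Determinism and numerics

Every stochastic step derives its seed from a single root seed through named
substreams (a small deterministic string hash below 2³¹), so one seed fixes
the entire study; the CLI test asserts byte-identical output files across
repeated runs.  Floating-point output is written with `%.10g`.  Key
numerical safeguards: ridge-stabilized normal equations, clipped linear
predictors, `log1p`-form deviances, Poisson limits at tiny dispersions, and
golden-section/parabolic refinement of all grid searches.

## 11. Limitations

- The consensus intersection controls FDR conservatively but gives up a
  little power relative to either single test by construction.
- The tagwise shrinkage uses a quadratic log-scale penalty rather than the
  weighted-likelihood empirical Bayes of some established packages; results
  agree in the prior-df limits but can differ slightly at moderate prior df.
- Library-size offsets assume fragment counts scale with sequencing depth;
  no GC or mappability correction is applied.
- The generator's ground truth is defined at the mean level; very
  low-abundance exons can be truly differential yet undetectable at
  realistic depth, which the sensitivity metrics reflect.
- ORA treats genes as exchangeable; exon counts per gene are not modelled
  in the null.
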