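# Methods

## Study design and model

The pipeline targets a paired two-site, two-group design: every subject
contributes one fimbrial and one proximal methylation profile, subjects
belong to either the mutation-carrier group or the control group, and
interest lies in CpGs whose within-subject site difference is specific
to carriers. All analysis operates on beta values (methylated-signal
fractions in [0, 1]); input matrices are taken as background-corrected,
and no normalization is applied.

### Quality control and imputation

An entry counts as detected when its detection p-value is ≤ 0.05 (and
the beta value is present). Samples with < 80% detected probes are
removed first; probes detected in < 95% of the *remaining* samples are
removed second — the order matters and is fixed as samples-then-probes,
which makes the filter idempotent. Entries that still fail detection are
replaced by probe-space KNN imputation with k = 5: the neighbour
candidates are probes with fully detected rows, nearness is Euclidean
distance between probe rows over the samples where the target row is
observed, and the imputed value is the mean of the k nearest rows'
values in the failed sample. Distance ties are broken by probe id in
lexicographic order so results are machine-independent (the large-matrix
distance expansion recomputes exact distances near the k-th value before
tie-breaking, since the fast expansion loses exact ties to cancellation
noise). The distance metric and neighbour space are a convention choice
— the standard microarray one — and are isolated behind `knn_impute`.

### Moderated paired test

The per-group test is a one-sample moderated t on the within-subject
differences d_g = β_fimb − β_prox. With n pairs, per-probe mean d̄_g and
unbiased variance s²_g (df = n−1), the prior (d₀, s₀²) is estimated by
the closed-form moment estimator on the log variances: with
e_g = log s²_g − ψ(df/2) + log(df/2), the excess of Var(e_g) over
ψ′(df/2) equals ψ′(d₀/2), solved by Newton inversion of the trigamma
function, and s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)). When the observed
spread does not exceed the chi-square sampling noise the prior is taken
infinitely informative (d₀ = ∞, s̃² ≡ s₀², normal reference
distribution). Otherwise s̃²_g = (d₀s₀² + df·s²_g)/(d₀ + df),
t_g = d̄_g/(s̃_g/√n), two-sided p from t with d₀ + df degrees of
freedom. The test suite cross-checks this against the Bioconductor
limma reference implementation (agreement to 1e−10) and against an
independent per-probe re-derivation of the closed forms.

The paired one-sample formulation is equivalent to a two-condition
linear model with subject blocking when all pairs are complete, and is
exactly testable; subjects missing either site are excluded from the
group (logged). The control-group FDR is computed over all probes, not
only over carrier-significant probes.

### DMP calling and heterogeneity

DMPs are probes with q_carrier < 0.05 (Benjamini–Hochberg within group),
q_control ≥ 0.05, and |median over carrier subjects of Δβ| > 0.03; all
threshold comparisons are strict. Direction is hyper for a positive
median difference. For each called DMP the fraction of subjects whose
Δβ exceeds 0.1 (and 0.2) in the DMP's direction is reported, averaged
over DMPs — a summary of between-subject heterogeneity of the change.
Single-array cell-line contrasts bypass the test entirely and threshold
the raw difference (strictly), with per-line thresholds supplied by the
caller.

### Gene and gene-set enrichment

The per-gene binomial test uses the array-wide rate
π = (#significant CpGs in the direction stratum)/(#CpGs in the
universe); a gene with n CpGs and x significant gets the one-sided
upper tail P(X ≥ x | n, π), BH-corrected across genes. Probes annotated
to several genes count once per gene; intergenic probes belong to the
universe but to no gene. Gene-set enrichment is a one-sided Fisher exact
test per named set over the universe of genes with ≥ 1 CpG on the
array; degenerate margins return p = 1 with the odds ratio flagged NaN.
Only the enrichment direction is tested (depletion is not computed) and
BH is used for both stages.

### Region (peak-track) enrichment

The test list is the top-1,000 called DMPs per direction by |median
Δβ|, boundary ties broken by probe id. 1,000 background sets are drawn
without replacement, each reproducing the test list's exact cell counts
over the joint (gene relationship × CpG-island relationship) bins, from
the non-test probes of each bin (excluding the test probes avoids
self-overlap bias; an under-populated bin is a hard error naming the
bin). A probe at 1-based position p overlaps a half-open 0-based
interval [start, end) iff p−1 ∈ [start, end). The binomial success
probability is pooled across all background sets
(p̂ = Σ counts / (n_sets × n_test)) and the p-value is the upper tail
P(X ≥ observed) at Binomial(n_test, p̂) — the pooled construction is
isolated in `enrichment_test` so a rank-based alternative can be
swapped in. Benjamini–Yekutieli correction is applied across all
(tissue × mark) tests of one input list; one background family is drawn
per list and reused across tracks, which is valid because backgrounds
depend only on the annotation. A zero background rate with a positive
observed count is floored at 1e−300 and logged.

### Top-k overlap of contrasts

Contrast effects are differences of per-group medians (a single-sample
group reduces to that sample), the top-k lists take the k largest
signed effects with lexicographic tie-breaks, and the 2×2 overlap table
over the shared universe is tested one-sided by the hypergeometric
upper tail. The sample odds ratio uses the Haldane–Anscombe 0.5
correction when a cell is zero, and the 95% CI is the Woolf logit
interval — chosen over conditional-likelihood intervals for simplicity
and isolated in `fisher_overlap`. The universe is the set of probes
surviving QC in both contrasts, configurable.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, not any
particular cohort's content. Defaults (all configurable):

- 30 carrier + 30 control subjects, one fimbrial and one proximal
  sample each; 20,000 probes; 500 carrier-only and 100 shared spiked
  probes with |Δβ| = 0.10; 81% of spikes hypomethylated in fimbrial
  tissue, mirroring the strong hypo-dominance such comparisons show.
- Per-probe baseline means m_g ~ Beta(0.85, 0.85) clipped to
  [0.02, 0.98] — a bimodal profile typical of array betas. Observed
  values draw from Beta(mν, (1−m)ν) with common precision ν = 200
  (sd ≈ √(m(1−m)/(ν+1)), ~0.035 at m = 0.5); the per-probe variance
  structure of real data is unknown, so ν is a free, documented choice.
  Spiked probes' baselines are re-drawn uniformly from
  [0.05+Δ, 0.95−Δ] so the planted shift is never attenuated by
  clipping.
- Entry-wise missingness at rate 0.005 (detection p drawn > 0.05);
  optional sample dropout masks a contiguous block of ~25% of probes so
  the sample fails the 80% coverage rule — together they exercise both
  QC passes.
- A single synthetic chromosome with probe spacing uniform in
  [800, 1200] bp; genes laid out as consecutive probe blocks
  (1 + Poisson(9) probes per gene) separated by intergenic gaps; ~3% of
  gene probes also map to the neighbouring gene; gene-relationship and
  CpG-island categories drawn with manifest-like frequencies.
- Peak tracks cover each probe independently at rate 0.10; enriched
  tracks cover *spiked* probes at 3× that rate. Peaks are ±200 bp
  around the probe — less than half the minimum probe gap, so a peak
  never reaches a neighbouring probe and per-probe coverage is exactly
  its Bernoulli draw.

What the generator does **not** model: chip/batch effects, age-related
drift, cellular-composition heterogeneity, probe cross-reactivity,
spatially correlated methylation (neighbouring-CpG co-methylation), or
realistic multi-chromosome genomes. Passing recovery tests therefore
demonstrate correctness of the inference machinery under the stated
noise model, not robustness to those real-data complications.

## Numerical and design notes

- FDR procedures delegate to `statsmodels` (`fdr_bh`, `fdr_by`);
  Fisher/hypergeometric/binomial tails delegate to `scipy.stats`. Hand
  step-up computations and exhaustive enumeration serve as oracles in
  the test suite.
- Probes constant across all subjects make the variance-prior fit
  degenerate and raise an error rather than returning NaNs.
- `select_top_probes`, `top_k_by_delta` and the KNN neighbour choice all
  break ties by probe id so every output is reproducible bit-for-bit
  from the seed; the pipeline manifest records SHA-256 hashes to make
  this checkable.
- Evaluation problem sizes: the recovery evaluation runs the full
  default design (20,000 probes, 60 subjects, several seeds); the
  region-enrichment calibration/power evaluation uses 6,000 probes with
  500-probe test lists (200 background sets in the test suite, 1,000 in
  the reproduction script); the contrast-overlap evaluation uses 8,000
  probes with k = 800 (k ≈ 10% of the universe, keeping the expected
  null overlap well populated). These sizes are the package's chosen
  evaluation design and are stated here so results are interpretable.

## Known limitations

- The moderated test assumes approximately normal within-subject
  differences; for betas near 0 or 1 the bounded support induces
  skew that the test ignores (M-value transforms are out of scope).
- The binomial gene test treats CpGs within a gene as independent;
  co-methylation inflates its significance on real data.
- The pooled-background binomial in the region enrichment understates
  the variance of the background distribution when probe coverage is
  spatially clustered; the reported background mean/sd allow a
  diagnostic check.
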