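# Methods

## Model

Each pathway `P` with member genes `g_1..g_N` restricts the log2-expression
matrix to an `N × E` block. The sample covariance of the normal cohort,
`C`, is treated as a point on the manifold of symmetric positive-definite
(SPD) matrices equipped with the affine-invariant metric, whose geodesic
distance is

    d(C, A) = || log(C^{-1/2} A C^{-1/2}) ||_F = sqrt( Σ_n log² λ_n ),

with `λ_n` the eigenvalues of `C⁻¹A`. A patient's score on `P` is the
distance between `C` and the "leave-one-in" covariance `A_i` re-estimated
with that patient appended to the normals: the displacement a single extra
sample causes in the reference covariance, measured along the manifold
rather than in Euclidean matrix space. Equivalently, the score is the
Euclidean norm of the tangent-space image of `A_i` at `C` in the minimal
vectorization (upper triangle of the whitened log, off-diagonal entries
scaled by √2); the √2 weighting is what makes the tangent norm equal the
geodesic distance, and the equality is enforced by test.

All matrix logarithms, exponentials and square roots go through symmetric
eigendecomposition of whitened products `C^{-1/2} A C^{-1/2}`, never the
nonsymmetric product `C⁻¹A`: the two are similar matrices with identical
eigenvalues, but only the whitened form is numerically symmetric. The
nonsymmetric form survives as an independent brute-force oracle in the
test suite.

Assumptions the score inherits from this construction:

- covariance (second-moment structure plus the mean-shift contribution of
  the appended sample) is where dysregulation shows; a perturbation that
  changes neither the mean nor the covariance of pathway genes is
  invisible;
- the normal cohort is homogeneous enough for a single reference
  covariance to be meaningful;
- one patient's score depends only on that pathway's genes — changing
  other genes leaves the score bit-identical (tested).

## Scoring normal samples

Appending a sample that is already in the reference moves the covariance
nowhere, so normal samples are scored by jackknife: the reference for
normal `s` is the covariance of the other `E−1` normals and the perturbed
point is the covariance of all `E` normals. This mirrors the tumor
construction — the background always excludes the scored sample. A
`duplicate` mode (append a literal copy of `s` to the full reference) is
exposed for comparison; jackknife is the default because duplication
shrinks all normal scores toward a pure sample-size artifact.

## Covariance regularization

Pathway gene counts routinely exceed normal cohort sizes (real cohorts can
have as few as 5 adjacent-normal samples), making the raw sample
covariance singular and every manifold operation undefined. The estimate
is therefore the `ddof=1` sample covariance shrunk toward `μI`
(`μ` = mean diagonal) with an analytic Ledoit–Wolf-style intensity,
followed by an eigenvalue floor of `1e-6 · trace/N` (absolute `1e-6` for
an all-constant block) as a last-resort repair. Two deliberate choices:

- the intensity is estimated **once per pathway from the normal cohort**
  and reused for the reference, every leave-one-in covariance and every
  jackknife covariance. A per-matrix analytic intensity would regularize
  reference and perturbed points differently, and the difference would
  masquerade as dysregulation signal;
- when the intensity is at least `1e-6` the floor provably cannot trigger
  (`λ_min ≥ α·μ` for a PSD sample covariance), so the repair path is
  skipped without changing the result.

Shrinkage mode (`lw`, `fixed`, `none`) and intensity are configurable; the
SPD validator accepts matrices symmetric to `1e-10` (relative) with
`λ_min > 1e-12 · λ_max` and rejects everything else rather than repairing,
because repair belongs to the covariance estimator.

## Downstream statistics

**Dysregulation calls.** Tumor `i` is dysregulated on `P` iff
`score > mean + k·sd` of the normal scores (strict inequality, `sd` with
`ddof=1`, floored at `1e-12` so tied normal scores cannot produce a
zero-width threshold). `k = 2` by default — under a roughly Gaussian null
this calls ~2–4% of normal-like samples, consistent with the null
calibration measured by the acceptance script. Stored thresholds reproduce
the calls exactly when reapplied; scores are serialized at full double
precision (and parsed back with round-trip float parsing) to keep that
true across files.

**Reproducibility score.** `RS = N² / Σ_{a,b} (Sim(X_a,X_b) −
Sim(A_a,A_b))²` over all ordered sample pairs, `Sim` the cosine
similarity of sample columns. The diagonal contributes zero, so including
it is a bit-reproducibility convention, not a modeling choice. A zero
denominator returns `+inf` with a logged warning.

**Jaccard overlap.** `|u∩v| / |u∪v|`, with two empty sets defined as 0.
The set formula gives 1 for identical sets; the pan-cancer overlap heatmap
zeroes the diagonal as a display convention (`jaccard_matrix`), keeping
the statistic itself honest.

**Prognostic screen.** Per pathway, a standard two-group log-rank test
(risk sets with ties grouped at identical times, via lifelines) comparing
survival of dysregulated vs near-normal patients; pathways with raw
`p < α = 0.05` are candidate biomarkers, with BH-adjusted values reported
alongside for users who want FDR control. Pathways with an empty group are
excluded with a reason, never fatal.

**Clustering benchmark.** Repeats `R` times (seeded): subsample tumors and
normals, score them, rank pathways by a Welch t-test on scores with BH
adjustment (a self-contained substitute for a moderated-statistics fit on
the score matrix; the selection is config-switchable), keep the top 10,
Ward-cluster the samples on those rows (Euclidean distance, cut at 2) and
record the adjusted Rand index against the true labels. Features enter the
clustering as raw scores; standardizing them was evaluated and was less
robust across seeds, because score spread itself carries signal here.

## Synthetic cohorts

The generator emulates the statistical structure the score exploits, not
RNA-seq noise realism. Normal samples are multivariate normal in
log2-expression space with unit variances, exchangeable correlation
`r = 0.3` inside each pathway's gene block (so a covariance inflation is
detectable by a covariance-based score), independence across blocks, and
unassigned noise genes; per-gene baseline means are drawn once around 6.
Tumors are identical except that in a designated fraction of pathways
(default 25%) the dysregulated tumors receive a mean shift `δ` (SD units,
default 1) and covariance scaled by `ρ` (default 2). Survival is
exponential with baseline hazard 1/1000 per day, multiplied by a hazard
ratio (default 2) for truly dysregulated patients, administratively
censored at 3000 days (~86% events).

By default every tumor carries the perturbation (`dysregulated_fraction =
1`), matching the generator's contract that tumors differ from normals on
perturbed pathways. The prognostic-screen scenario sets it to 0.5: with no
within-tumor heterogeneity the dysregulated group absorbs every tumor,
the near-normal group is empty and every pathway is excluded, so the
screen is only meaningful when some tumors remain normal-like. If no
pathway is perturbed, no sample is dysregulated and all hazards are equal
(the global null).

What passing tests on these cohorts do **not** show: robustness to count
noise (negative binomial), batch effects, normal-cohort heterogeneity,
gene-identifier mismatches, or overlapping pathways (an overlap option
exists but the canned scenarios partition genes).

### Canned scenarios and problem sizes

- `fixture_small()` — 200 genes in 20 pathways of 10, 30+30 samples, 5
  perturbed pathways at `δ=1.5, ρ=2`, fixed seed; end-to-end scoring in
  well under a second.
- `benchmark_cohort()` — same structure with 60+60 samples, so the
  30+30-subsample clustering benchmark varies across repeats and its
  median is a real median.
- `survival_screen_cohort()` — 20 pathways, 50 normals, 200 tumors, half
  of them dysregulated, hazard ratio 2.
- `null_cohort()` — 1000 pathways, no perturbation, uniform hazard, 1200
  tumors. The tumor count is chosen so the per-pathway dysregulated
  groups (~50 at `k = 2`) are large enough for the log-rank chi-square
  approximation to hold: in direct simulation the test over-rejects by
  roughly a percentage point at group sizes below ~25, which is a property
  of the asymptotic approximation, not of the screen.

## Numerical and degenerate-input conventions

- Eigenvector sign/order ambiguity is irrelevant: every output is a
  function of eigenvalues or full spectral reconstructions.
- Scoring is deterministic; the only randomness anywhere is seeded
  subsampling in the benchmark and the cohort generator.
- Degenerate inputs (all-constant blocks, empty call groups, zero-norm
  columns, pathways below the minimum gene count after intersection)
  either return the documented sentinel or are skipped with a logged
  reason; they never crash a whole-cohort run.
- Duplicate gene rows at load time keep the first occurrence; gene ids
  match by exact string after whitespace trimming (no alias resolution).

## Known limitations

- The score conflates mean-shift and covariance-change signal; it reports
  displacement magnitude, not direction or sign.
- With very few normals the jackknife references are noisy and normal
  scores (hence thresholds) are wide; the `min_normals` default of 10
  reflects the cohort-inclusion convention for this kind of analysis.
- Raw log-rank p-values at `α = 0.05` screen liberally by design;
  BH-adjusted values are emitted for stricter use.
- Pathway topology is ignored: scoring uses gene membership only.
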