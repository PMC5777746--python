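# Methods

This note documents the models, estimators and design choices behind each
stage, the synthetic-data generator's assumptions, and the known
limitations. It states nothing the test suite does not itself compute.

## Probe-set classification

A probe set is called lncRNA when at least one line of evidence supports
it — an `NR_`-prefixed RefSeq transcript accession, or an Ensembl biotype
in the retained set {`lincRNA`, `processed_transcript`, `macro_lncRNA`,
`misc_RNA`} — and nothing vetoes it. Vetoes come in two strengths:

* **Conflict** (excluded explicitly): one database supports lncRNA while
  the other asserts `protein_coding` or a removal-set biotype
  (pseudogene family, rRNA, miRNA, tRNA, snRNA, snoRNA and kin). Such
  probes measure transcripts whose identity the two references dispute,
  so no direction of resolution is defensible.
* **Same-database veto**: a multi-gene probe set whose own Ensembl
  annotation mixes a retained biotype with a removal biotype is excluded
  as short/pseudogene rather than as a conflict — both claims come from
  one source.

Multi-valued annotation cells qualify a probe if *any* transcript or gene
qualifies, but any removal hit vetoes — the conservative reading.
Biotype matching is case-insensitive; the pseudogene family is matched by
substring so that every `*_pseudogene` flavour is caught without
enumeration. Unknown biotypes fall to a configurable default (excluded)
and are logged, never silently dropped. Gene identity for counting keys
on the gene symbol, falling back to the first retained Ensembl gene id —
this is what makes two probe sets of one gene count once.

## RMA preprocessing

**Background.** Observed intensity is modelled per array as
`o = s + n`, signal `s ~ Exp(alpha)`, optical noise `n ~ N(mu, sigma^2)`.
Completing the square shows the signal posterior is `N(a, sigma^2)`
truncated to `s >= 0` with `a = o - mu - sigma^2 * alpha`; the corrected
value is its mean `a + sigma * phi(a/sigma) / Phi(a/sigma)`, evaluated in
log space for stability (the Mills ratio degenerates numerically below
`a/sigma ≈ -30`). The map is strictly increasing in `o` and strictly
positive, so log2 is always defined downstream.

Parameters are estimated per array by a mode-based heuristic: the noise
mean is the intensity-density mode, refined in two stages because a
single kernel-density pass over the heavy-tailed intensity scale is
oversmoothed (Scott-rule bandwidth on a range spanning two orders of
magnitude buries the background peak mid-signal); the refinement re-runs
the density on the values below the rough mode, where the optical peak
lives. The noise sd comes from the half-spread below the mode (inflated
by sqrt(2) to a full-normal sd) and the signal rate from the exponential
MLE on exceedances. All three can be overridden per array, which the
deterministic tests use. The estimator presumes a visible background
peak, i.e. a substantial fraction of unexpressed probes — true of real
arrays and of the generator's defaults (below); on a hypothetical array
where every probe carries strong signal the mode estimate would sit in
the signal mass and compress low-intensity fold changes.

**Quantile normalisation** forces every array onto the across-array mean
of order statistics. Ties receive the target distribution interpolated
at their average rank, so ties stay ties; idempotence is exact for
tie-free columns and approximate under ties (re-averaging shifts the
target by the tied values' spread).

**Median polish** fits `log2 x = overall + probe + array + residual` by
iterated row/column median sweeps (row sweep, fold the col-effect median
into the overall, column sweep, fold the row-effect median in), stopping
when the absolute-residual objective stalls (relative tolerance 1e-10,
max 32 sweeps). Per-array expression is `overall + array effect`.
Same-size probe sets are polished as one stacked batch: sweeps past a
block's own fixed point are no-ops, so batching changes nothing but
speed. Note the decomposition is not unique in general — blocks with
even dimensions can plateau at equal-objective fixed points, where two
correct implementations may settle on different overall/effect splits;
the oracle tests therefore compare on odd-column instances, which
converge uniquely in practice. A single-probe set passes through as its
log2 values with zero residuals.

## NUSE / RLE quality control

The unscaled standard error of probe set g on array j is
`1.4826 * median_i |residual_ij| / sqrt(#probes)` over the set's probes —
a median-absolute-deviation summary of the polish residuals rather than a
full probe-level robust linear model, which keeps the estimator
self-contained while preserving what the metric responds to (per-array
residual spread). Each probe set's SE row is scaled by its across-array
median so the row median is 1 (sets with a single probe carry no
replicate information and are skipped). RLE is log2 expression minus the
probe-set's across-array median. Per array, both metrics are summarised
by median and IQR.

Control limits are Tukey fences — median ± 1.5 × IQR across arrays — on
the NUSE median and the RLE IQR, both configurable. An array is removed
only when it breaches both ("joint rule"); preprocessing is then re-run
on the retained arrays, since normalisation and polish are
sample-dependent. With fewer than 3 arrays the fences are meaningless
and QC is skipped with a warning flag. Because the fences adapt to the
cohort's spread, a tight cohort can flag borderline good arrays — e.g.
when a small control group sits slightly off the case-dominated RLE
reference — which mirrors how aggressively this style of QC prunes real
studies; the joint rule is the guard against single-metric
false removals.

## Differential screen

Pooled-variance Student *t* (not Welch), two-sided, on log2 expression;
`log2fc = mean(case) − mean(control)`. Degenerate zero-variance probes
get the (t=0, p=1) or (p=0, flagged) sentinels. FDR is
Benjamini–Hochberg. A call requires all three: FDR < `fdr_max` (0.20),
p < `p_max` (0.01), |log2fc| ≥ log2(`fold_min`) (fold 2), the "unfolded
change" read as the linear expression ratio. Clustering is unweighted
average linkage on 1 − Pearson correlation between arrays (falling back
to Euclidean, with a warning, when a constant profile makes correlation
undefined); arrays are sorted lexicographically first so merge ties
resolve deterministically.

## Overlap and ΔΔCt

Gene direction is by unanimity over called probes; disagreement yields
`ambiguous`, which is reported but excluded from concordance — dropping
it silently would hide real intra-dataset inconsistency. The
cross-dataset join keys on gene symbol (Ensembl id fallback). ΔΔCt uses
replicate means per (gene, group) cell:
`ΔΔCt = (Ct_t − Ct_ref)_case − (Ct_t − Ct_ref)_control`, relative
expression `2^(−ΔΔCt)`; it is invariant to any constant added to all Ct
values. No amplification-efficiency (Pfaffl) correction is applied.

## Cis window

Coordinates are 1-based inclusive and strand-agnostic: upstream/downstream
mean lower/higher coordinates, because the worked-example table labels
the lower-coordinate neighbour "upstream" without strand. The gap counts
bases strictly between nearest edges (`b1 − a2 − 1`); the window test is
`gap <= window` (boundary inclusive, "within 10 kb"), measured
edge-to-edge rather than from transcription start sites — the choice that
reproduces all published labels.

## Trans screen

Spearman rho is the Pearson correlation of average ranks. The p-value is
the exact two-sided permutation probability for n ≤ 9 — the tie-free null
distribution is enumerated once per n and cached; tied inputs are
enumerated directly — and the t approximation
`t = rho sqrt((n−2)/(1−rho²))` above, where exact enumeration becomes
both unnecessary and expensive. Correlations pool cases and controls:
the screen asks about co-expression across the whole cohort, and
stratifying would halve the already small n. Constant rows have
undefined rank correlation and are flagged, never scored. Pair screening
is vectorised (standardised rank matrices multiplied) with the p-value
computed only for pairs passing the |ρ| gate.

## Enrichment and motif scanning

EASE is the upper-tail hypergeometric probability with one gene removed
from the query/term overlap: P(X ≥ k−1) for X ~ Hypergeom(N, K, n), and
1.0 whenever k ≤ 1 — a deliberate penalty on single-gene support. Fold
enrichment is (k/n)/(K/N). The background defaults to all annotated
genes of the analysed array (overridable); no multiple-testing correction
is applied beyond the EASE ≤ 0.1 and count ≥ 2 filters, matching the
screening character of the stage.

PWMs hold per-position log-odds over {A, C, G, U}; count or frequency
matrices are converted with a uniform 0.25 background and 0.01
pseudocount. The relative score of a window normalises its summed weight
over the matrix's attainable range, `(S − S_min)/(S_max − S_min)`, so
thresholds are comparable across matrices of different widths and scales.
Scanning slides every matrix over every sequence (T read as U, no
reverse-complement pass — the targets are single-stranded RNA) and emits
windows at relative score ≥ 0.8, with a 1e-12 tolerance so exact-boundary
scores survive floating-point rounding. Shared proteins are the
intersection of per-sequence hit sets.

## Synthetic data

The generator emulates a two-platform mouse array study at its actual
scale: 1300 probe sets × 11 probes on 18 arrays (14 case, 4 control).
All randomness derives from one seed through four independent child
streams (annotation, experiment, genome, sequences), so regenerating one
component never perturbs another and same-seed outputs are byte-identical.

* **Annotation**: probes drawn across six classes (coding, three lncRNA
  evidence sources, conflict, short RNA) with configurable fractions
  (defaults 0.40 lncRNA split evenly, 0.05 conflict, 0.05 short); a gene
  pool at 70% of the probe count produces multi-probe genes.
* **Experiment**: per-set log2 baselines uniform on (7, 13) — expressed
  probe sets sit well above background, as probe sets retained for
  screening do on real chips — with 25% of sets drawn unexpressed
  (baselines 2–4, i.e. essentially optical background). The unexpressed
  fraction is what makes the background-peak parameter estimate
  identifiable, exactly as on real arrays. Linear intensity is
  `2^(baseline + probe affinity + N(0, 0.25)) + optical N(40, 6)`.
  Planted DE sets shift case arrays by ±2 log2 units; one corrupted
  array (drawn from the case group, so its removal cannot empty the
  small control group) has its log2 noise inflated 4×.
* **Trans pairs**: two probe sets share a Gaussian latent driver whose
  correlation is the analytic Gaussian-copula inverse of the target
  Spearman coefficient, `r = 2 sin(pi * rho_s / 6)` — a
  monotone-transform construction. Because the sampling sd of Spearman's
  coefficient at n = 18 is ≈ 0.06, the population-level construction
  alone would scatter realised coefficients far beyond a ±0.05 band;
  the planted contract is therefore enforced on the *realised* sample
  rank correlation of the drawn signals, by rejection sampling with an
  interior ±0.03 margin that leaves headroom for downstream measurement
  noise. The realised value is recorded in the ground truth.
* **Genome**: each lncRNA owns an exclusive slot wide enough that a gene
  planted near it cannot qualify for any other lncRNA; near genes get
  edge gaps uniform on [0, window] (or overlap), far genes sit in slot
  margins more than one window from every locus — so the qualifying
  pairs are exactly the planted ones, with an infeasibility error when
  chromosomes are too small.
* **Sequences**: uniform-background RNA with sharply peaked count-matrix
  motifs (85% consensus weight per position) embedded at recorded,
  mutually disjoint offsets; a 0.8-threshold scan must recover every
  placement.

What the generator does **not** emulate: probe GC and sequence-affinity
structure, scanner spatial artifacts, batch effects, correlated
biological modules beyond the planted pairs, mappability errors in the
annotation, or binary CEL encoding. Passing recovery tests therefore
demonstrates the pipeline's correctness under the stated signal model,
not robustness to every artifact of archived array data.

## Numerical choices and degenerate inputs

Medians of even-length vectors are the mean of the central pair
throughout (determinism). Probe sets with one probe pass through
summarisation; sets with fewer than two probes are excluded from NUSE.
Sequences shorter than a matrix yield zero hits with a log line, not an
error. Degenerate PWMs (all windows equal) and constant vectors in
correlation are errors/flags, never silent numbers. Validation errors
name the offending column, position or probe.

## Test and acceptance problem sizes

The oracle suites run on deliberately tiny instances (blocks up to 7×5,
backgrounds N ≤ 12 for full enumeration, n ≤ 6 for permutation nulls)
where brute force is exact. Parameter recovery uses the default study
size for 25 fixed seeds; null calibration uses a 300-set null experiment
with 100 label permutations and 500 independent-noise pairs at n = 10 —
sizes chosen so the whole suite completes in a few minutes while keeping
every estimate's Monte-Carlo error far from its acceptance margin.
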