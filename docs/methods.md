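# Methods

This note documents the models, conventions, and numerical choices made
in `prognet`, in the order data flows through the pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Conventions

* Genomic coordinates are 0-based half-open `[start, end)` everywhere
  (BED convention); any 1-based source must be converted on load.
* Expression values are log2 scale unless a function documents an FPKM
  (non-negative, linear) contract, as the variation filter does.
* Survival times are months. The clinical loader takes a
  `time_unit` flag (`months`/`years`) because public breast-cancer
  cohorts disagree on units and files rarely say.
* Missing expression values are rejected by default; an explicit
  `allow_na` mode mean-imputes per feature and logs the count. Silent
  imputation hides data problems; refusing by default surfaces them.

## Synthetic study

All inputs come from `prognet.simulate`, driven by a single root seed.
Substream seeds are derived with `numpy.random.SeedSequence(seed,
spawn_key=(k,))` and PCG64, so each generator can be regenerated
independently and identically across platforms. Every generator returns
its ground truth beside the data; analysis code never reads the truth.

**Knockdown screen** (`gen_knockdown_experiment`): two cell lines, each
with a control arm and two independent shRNA arms, 6 replicates per arm,
1000 probes with Uniform(4, 12) log2 baselines and Gaussian noise
(sd 0.1). 30 planted genes shift by −2 log2 units in both shRNA arms of
both cell lines (the direction convention is down-in-knockdown; a
non-positive effect is an error). These sizes mirror a realistic
two-line dual-hairpin microarray screen in which the knockdown effect is
large relative to technical noise.

**Patient cohort** (`gen_patient_cohort`): 509 patients. Signature genes
load on one latent risk factor with loading 0.7 (so pairwise member
correlation ≈ 0.49 and the meta-gene average is a better risk readout
than any single gene — the point of a meta-gene); background genes are
independent. Event times are exponential with a 3-fold hazard for
patients above the meta-gene median (binary-group exponential model,
chosen so Cox/log-rank recovery has a closed-form target). Censoring is
an independent Uniform(0, c) time with c calibrated by bisection on the
closed-form censoring probability to hit the requested rate (default
0.3); `censor_rate=0` disables censoring.

**Grade datasets** (`gen_grade_datasets`): k = 10 cohorts; each cohort's
true standardized mean difference is drawn Normal(0.8, 0.2²), group
sizes Uniform{10..40} per grade, unit-variance Gaussian within group.
Requesting group sizes below 10 is an error because such cohorts are
ineligible by design.

**Toy genome** (`gen_genome_peaks`): 3 chromosomes of 1 Mb, 200 genes
with 3-exon models, four transcription-factor peak sets of 300 peaks of
400 bp. A `cobind_fraction` of genes receives one peak from each factor
inside its promoter window; these four peaks share a per-gene summit
with ±peak_len/4 jitter. The shared summit is deliberate: coordinated
binding in real ChIP data produces genomically overlapping peaks, and
independent placement anywhere in a 4.5 kb window would make planted
co-binding invisible to a base-pair intersection statistic. Remaining
peaks are uniform on the genome. 150 H3K4me1-like regions (0.8–2 kb) are
placed uniformly; half also receive an H3K27ac-like region ("active").

**FPKM experiment** (`gen_fpkm_knockdown`): 2000 genes, 8 control and 8
knockdown samples (two per factor), log-normal FPKM with log2 sd 0.5;
50 up and 50 down planted genes at ±2 log2 units. 40% of non-planted
genes are stably expressed (log2 sd 0.05) so the variation filter has a
realistic job, qualitatively mirroring the roughly-half survivor rate
seen in real RNA-seq variation filtering.

What the generators do **not** model: probe-level intensity physics,
array batch effects, non-proportional hazards, competing risks,
copy-number-driven expression, peak-width heterogeneity, or read-level
noise. Passing tests therefore demonstrate correctness of the statistics
and plumbing under a clean generative model, not robustness to every
artifact of real cohorts.

## Derivation funnel

Order of stages: dual-shRNA significance (Welch t-test, p < α under
*both* shRNAs with agreeing sign; α defaults to 1e-6), probe→gene
mapping, per-probe prognostic screen, two-line intersection with the
down-in-both direction rule, poor-prognosis expression filter. The
significance-then-map-then-screen order is used throughout; funnel
counts are monotone non-increasing by construction within a cell line.

Choices where the procedure was genuinely open:

* The differential test is Welch's t-test; the two-color platform's
  original significance model is not reproducible from summary matrices.
  α is a flag.
* The prognostic screen splits each feature at its median (values
  strictly greater than the median go high — deterministic under ties);
  a quantile split is available. Features whose split leaves fewer than
  2 samples on a side are skipped with a warning.
* Poor prognosis = event before a 60-month horizon; good = event-free
  with follow-up ≥ 60 months; patients censored early are excluded. The
  horizon is a flag since the underlying grouping rule is a convention.
* Probe suffix priority is `_at` > `_x_at` > `_s_at`, exposed as a
  config knob because array-annotation practice varies.
* When several passing probes map to one gene with conflicting
  directions, the gene is dropped (logged) rather than guessed.

## Survival statistics

Log-rank: observed-minus-expected with hypergeometric variance summed
over distinct event times (terms with risk set 1 are skipped); z² equals
the χ²₁ statistic; the one-sided p-value Φ(−z) tests "signature-high is
worse", matching the direction in which poor-prognosis signatures are
read, with the two-sided p from χ²₁. A degenerate comparison with zero
variance (e.g. no events) returns a defined null result instead of NaN.

Cox: the binary-covariate special case fitted by Newton–Raphson on the
Breslow partial likelihood (the scalar score and information are closed
form). Convergence is |Δβ| < 1e-8 within 50 iterations. Monotone
likelihood is detected when all events fall in one group, when the
information vanishes, or when |β| exceeds 20; the result is flagged
rather than silently divergent. SE comes from the observed information;
the 95% CI is exp(β ± 1.96·se). Breslow (not Efron) is used because it
is the simplest standard choice; on tie-free data the two coincide,
which is how the implementation is cross-checked against lifelines.

Stratification defaults to a median split with ties going low; the
top-q-fraction rule is available because published cohort analyses vary
in their cutoffs.

## Grade meta-analysis

The per-cohort effect is Hedges' g*: pooled sd
s* = √[((n₁−1)s₁²+(n₂−1)s₂²)/(n₁+n₂−2)], g = (x̄₁−x̄₂)/s*, correction
(1 − 3/(4(n₁+n₂)−9)), and SE √[(n₁+n₂)/(n₁n₂) + g*²/(2(n₁+n₂−3.94))] —
the standard small-sample form, implemented exactly as printed above.
Combination is DerSimonian–Laird: moment τ² truncated at 0, RE weights
1/(seᵢ²+τ²), normal-approximation CI and two-sided p. REML (fixed-point
iteration started at the DL value) is available as `method="reml"`;
both estimators are cross-checked against R's metafor in the tests.
Eligibility: ≥ 10 grade I and ≥ 10 grade III tumors after deduplicating
patients (first sample kept); ineligible cohorts are excluded with a
logged reason, and fewer than two eligible cohorts is an error.
Per-gene effects are the default; a gene list is scored as a meta-gene.

## Peak genomics

Promoter windows are −2000/+2500 bp around the TSS, reflected on the
minus strand and clipped to the chromosome. A gene is bound when a peak
overlaps its window by at least `min_overlap` bp (default 1 — the
weakest defensible criterion, exposed as a flag). Peak classification is
a strict priority partition (promoter > exon > intron > active enhancer
> enhancer > intergenic), so per-factor category counts always sum to
the peak total. "Active enhancer" defaults to H3K4me1 ∧ H3K27ac; an
H3K27ac-alone rule is selectable because the two definitions coexist in
the literature.

The k-way intersection is computed by a sweep line over merged per-set
intervals: since each set is self-overlap-free after merging, summed
coverage depth equals the number of covering sets, and maximal depth-k
segments are the intersection regions. The reported "count" is the
number of such merged regions (the counting unit for intersecting peaks
is otherwise ambiguous). The implementation is required by the test
suite to agree exactly with a per-base-pair boolean-AND oracle.

The permutation null holds set 1 fixed and uniformly repositions every
peak of the remaining sets within its original chromosome, preserving
lengths and permitting collisions; a circular-shift null is available.
The empirical p uses the add-one estimator (1 + #{null ≥ obs})/(1 + B),
so p is never 0 and equals 1/(B+1) when the observed count is
unmatched. Because counts are integers, ties with the observed value
make the p-value mildly conservative; the uniformity check in the
acceptance suite uses genome/peak sizes with enough count spread that
this discreteness is negligible.

TSS coverage matrices bin ±10 kb around each TSS (bin width a divisor of
the window); each cell is the number of covered base pairs in that bin
(optionally score-weighted), minus-strand rows are reversed so bins run
5′→3′, and rows are ordered by the ranking factor's maximum peak score
in the window.

## Differential expression and GSEA

The variation filter keeps genes with (max+ε)/(min+ε) ≥ 1.5 and range
≥ 1 on the FPKM scale, ε = 0.001 guarding zero FPKMs. The t-test is
pooled-variance by default (Welch by flag) with BH step-up q-values via
statsmodels; zero-variance rows get p = 1 rather than NaN. Row 0–1
scaling maps constant rows to 0.5 (with a warning) so heat-map rows stay
defined.

Signal-to-noise is (μ_A−μ_B)/(σ_A+σ_B) with each σ floored at
max(0.2·|μ|, 0.2), the widely used desktop-GSEA convention (the floors
are module constants). Ranking ties break by gene id for determinism.
The enrichment score is the signed maximal deviation of the running sum
(hits weighted by |score|^p, p = 1; misses 1/(N−n_set)); when the
positive and negative extremes tie in magnitude to within 1e-12 the
positive one is reported — a documented tie rule the brute-force test
oracle shares. The phenotype-permutation p-value is one-sided with the
add-one estimator, NES divides the observed ES by the mean |null ES| of
the same sign, and for a single gene set the reported FDR reduces to the
nominal p (multi-set FDR is out of scope).

## Problem sizes in the verification suite

The acceptance checks run at the scales the package's guarantees are
stated at: 500 meta-analysis simulations, 1000 null survival cohorts of
n = 200, 200 Cox recoveries at n = 2000, 50 full funnel studies at
generator defaults, 100 random genomes for the interval oracle, 200
permutation-null runs at B = 199 (B = 999 for the identical-sets case),
and 1000 trials each for the BH and enrichment-score oracles. The whole
suite completes in about a minute on one CPU; these sizes were
chosen as the smallest at which the binomial tolerances quoted in the
tests are meaningful.

## Known limitations

* Only the binary-covariate Cox model is provided; no multivariate or
  time-varying extensions.
* The quantile-normalization tie rule (mean of reference values at tied
  ranks) is one of several reasonable conventions.
* The permutation null ignores chromatin accessibility structure; real
  co-binding enrichments are usually assessed against more constrained
  nulls.
* The synthetic generators make no attempt to reproduce any published
  cohort's gene membership or exact headline counts — they plant
  analogous structure so that recovery is checkable.
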