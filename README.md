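# prognet

A tested reimplementation of the computational pipeline behind
knockdown-derived prognostic gene signatures in breast cancer: deriving a
poor-prognosis gene set from dual-shRNA transcription-factor knockdown
screens, scoring patients with a meta-gene and quantifying prognosis with
survival statistics, combining tumor-grade effect sizes across cohorts by
random-effects meta-analysis, and quantifying coordinated genome binding
of four transcription factors (Fra-1/FOSL1, MYC, E2F1, TP53) from ChIP-seq
peak intervals. It is written for computational biologists who want each
of these steps as a small, well-specified, independently testable
operation rather than a monolithic script.

Because the original microarray, clinical, and ChIP-seq cohorts are
large and partly controlled-access, the package ships a first-class
synthetic-data module that generates every input the pipeline consumes
from a single seed, with planted ground truth (which genes were
knocked down, which patients are high-risk, which promoters are
co-bound). Every stage is therefore verifiable end to end.

## The statistics at the core

**Signature funnel.** Probes significantly changed by *both* independent
shRNAs (Welch t-test, p < 1e-6 each, agreeing sign) in each of two cell
lines are mapped to genes (one probe per gene, suffix priority
`_at` > `_x_at` > `_s_at`, remaining duplicates averaged), screened for
prognostic value on a training cohort (median-split log-rank p < 0.1),
intersected across cell lines keeping genes down-regulated in both, and
finally filtered to genes whose median expression is above the cohort
median in poor-prognosis patients (event before 60 months) and below it
in good-prognosis patients (event-free past 60 months).

**Survival.** A meta-gene is the unweighted per-sample mean of the
member genes' log2 values. High/low groups (median split, ties low) are
compared by the log-rank test, z = (O_A − E_A)/√V with hypergeometric
variance, one-sided p = Φ(−z) for "signature-high is worse", and by a
binary-covariate Cox proportional-hazards fit (Breslow ties,
Newton–Raphson, monotone-likelihood detection).

**Grade meta-analysis.** Per cohort, the grade III vs grade I
standardized mean difference with small-sample bias correction:

    s* = √[((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)]
    g  = (x̄₁ − x̄₂)/s*,   g* = (1 − 3/(4(n₁+n₂) − 9))·g
    σ̂(g*) = √[(n₁+n₂)/(n₁n₂) + g*²/(2(n₁+n₂−3.94))]

combined with a DerSimonian–Laird random-effects model (REML optional);
cohorts need ≥ 10 tumors per grade group, one tumor per patient.

**Peak genomics.** Genes are "bound" when a peak overlaps the
−2 kb/+2.5 kb strand-aware promoter window around the TSS by ≥ 1 bp.
Peaks are partitioned into promoter > exon > intron > active enhancer
(H3K4me1 ∧ H3K27ac) > enhancer (H3K4me1) > intergenic. The four-factor
intersection counts maximal regions covered by at least one peak from
every factor; its significance comes from a permutation null that
uniformly repositions peaks within their chromosome (lengths preserved),
with an add-one empirical p-value.

**Expression / enrichment.** FPKM matrices pass a variation filter
(≥ 1.5-fold and ≥ 1 absolute range), genes are tested control vs
knockdown by t-test with Benjamini–Hochberg step-up q-values, and gene
sets are scored by from-scratch GSEA: signal-to-noise ranking (σ floored
at max(0.2·|μ|, 0.2)), weighted running-sum enrichment score, phenotype
permutations.

## Worked example

```python
from prognet.simulate import SimConfig, gen_knockdown_experiment, gen_patient_cohort
from prognet.signature import derive_signature
from prognet.preprocess import collapse_probes
from prognet.survival import metagene_score, stratify, logrank_test, cox_hr_binary

cfg = SimConfig(seed=1)                      # 1000 probes, 30 planted, 509 patients
kd = gen_knockdown_experiment(cfg)           # two cell lines x (control, kd1, kd2)
cohort = gen_patient_cohort(cfg)             # survival cohort, hazard tied to meta-gene
sig, report = derive_signature(kd["A"], kd["B"], kd["probe_map"],
                               cohort["matrix"], cohort["records"])
print(report.to_string(index=False))
```

prints the stage-by-stage funnel:

```
                   stage  n_features
   differential_probes_A          30
   differential_probes_B          30
          mapped_genes_A          30
          mapped_genes_B          30
            prognostic_A          30
            prognostic_B          30
            common_genes          30
            down_in_both          30
poor_prognosis_signature          30
```

i.e. all 30 planted knockdown-dependent genes survive every filter and
no background gene sneaks in. Stratifying the cohort by the derived
meta-gene and testing survival:

```python
gene_cohort = collapse_probes(cohort["matrix"], kd["probe_map"])
scores = metagene_score(gene_cohort, sig.gene_ids)
groups = stratify(scores)                       # median split, ties low
...
```

```
one-sided log-rank p = 4.22e-31
HR = 3.51 (95% CI 2.80-4.39)
```

The signature-high half of the cohort has a ~3.5-fold hazard — the
generator planted a 3-fold hazard ratio on the true meta-gene, and the
derived signature recovers it (the estimate exceeds 3 because the
derived meta-gene split differs slightly from the planted one).

The same workflows are available from the shell via the `prognet`
command (`simulate`, `preprocess`, `derive-signature`, `survival`,
`meta-grade`, `peaks`, `de`, `gsea`); see `prognet COMMAND --help`.

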