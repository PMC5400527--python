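"""Synthetic data generators with planted ground truth.

Every generator is driven by a single root seed: per-generator substream
seeds are derived deterministically with :class:`numpy.random.SeedSequence`
spawn keys, so any one input can be regenerated independently and the
whole study is byte-reproducible (PCG64 generator throughout).

The generators emulate the study conditions of a dual-shRNA knockdown
signature screen in two cell lines, a 509-patient survival training
cohort, a ten-dataset tumor-grade comparison, a toy genome with four
transcription-factor ChIP peak sets and enhancer marks, and an 8-vs-8
control/knockdown FPKM experiment. Ground truth is returned alongside
each dataset and must never be consumed by the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    PeakSet,
    ProbeMap,
    SurvivalRecord,
)

__all__ = [
    "SimConfig",
    "gen_probe_universe",
    "gen_knockdown_experiment",
    "gen_patient_cohort",
    "gen_grade_datasets",
    "gen_genome_peaks",
    "gen_fpkm_knockdown",
]

# substream spawn keys
_KEY_UNIVERSE = 0
_KEY_KNOCKDOWN = 1
_KEY_COHORT = 2
_KEY_GRADE = 3
_KEY_GENOME = 4
_KEY_FPKM = 5

TF_NAMES = ("E2F1", "FRA1", "MYC", "TP53")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults set to the study
    conditions the pipeline is designed around."""

    seed: int = 0

    # dual-shRNA knockdown screen (two cell lines)
    n_probes: int = 1000
    n_planted: int = 30
    n_planted_up: int = 0
    kd_effect_log2: float = 2.0
    noise_sd: float = 0.1
    n_reps: int = 6

    # patient cohort
    n_patients: int = 509
    hazard_ratio: float = 3.0
    censor_rate: float = 0.3
    baseline_hazard: float = 0.008     # events per month in the low-risk group
    latent_loading: float = 0.7        # signature genes' loading on the risk factor

    # tumor-grade meta-analysis
    n_grade_datasets: int = 10
    planted_smd: float = 0.8
    tau: float = 0.2
    grade_n_min: int = 10
    grade_n_max: int = 40

    # toy genome / ChIP peaks
    n_chroms: int = 3
    chrom_len: int = 1_000_000
    n_genes: int = 200
    peaks_per_factor: int = 300
    cobind_fraction: float = 0.3
    peak_len: int = 400
    n_enhancers: int = 150
    active_enhancer_fraction: float = 0.5

    # FPKM control-vs-knockdown experiment
    n_fpkm_genes: int = 2000
    n_de_up: int = 50
    n_de_down: int = 50
    de_effect_log2: float = 2.0
    de_noise_sd: float = 0.5
    low_var_fraction: float = 0.4      # stably expressed genes (tight FPKM spread)
    low_var_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "n_probes", "n_planted", "n_reps", "n_patients", "n_grade_datasets",
            "n_chroms", "chrom_len", "n_genes", "peaks_per_factor", "peak_len",
            "n_enhancers", "n_fpkm_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if not (0 <= self.cobind_fraction <= 1):
            raise ValueError("cobind_fraction must be in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.n_planted + self.n_planted_up >= self.n_probes:
            raise ValueError("n_planted (+ n_planted_up) must be < n_probes")
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates per arm")
        if self.grade_n_min < 10:
            raise ValueError("grade group sizes below 10 violate dataset eligibility")
        if self.grade_n_max < self.grade_n_min:
            raise ValueError("grade_n_max < grade_n_min")

    def rng(self, key: int) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.Generator(np.random.PCG64(ss))


_SUFFIX_CYCLE = ("_at", "_at", "_at", "_at", "_at", "_at", "_at", "_s_at", "_x_at", "_at")


def gen_probe_universe(config: SimConfig) -> dict:
    """Gene/probe universe shared by the knockdown screen and the cohort.

    One source (two-color-array-like) probe and one target (suffix-bearing)
    probe per gene; target suffix classes cycle so collapsing is exercised.
    Returns genes, probe map, planted down/up gene sets.
    """
    rng = config.rng(_KEY_UNIVERSE)
    n = config.n_probes
    genes = [f"G{i:05d}" for i in range(n)]
    source = [f"A{i:05d}" for i in range(n)]
    target = [f"G{i:05d}{_SUFFIX_CYCLE[i % len(_SUFFIX_CYCLE)]}" for i in range(n)]
    pmap = ProbeMap(list(zip(source, genes, target)))
    planted_idx = rng.choice(n, size=config.n_planted + config.n_planted_up, replace=False)
    planted_down = sorted(genes[i] for i in planted_idx[: config.n_planted])
    planted_up = sorted(genes[i] for i in planted_idx[config.n_planted:])
    return {
        "genes": genes,
        "source_probes": source,
        "target_probes": target,
        "probe_map": pmap,
        "planted_down": planted_down,
        "planted_up": planted_up,
    }


def gen_knockdown_experiment(config: SimConfig) -> dict:
    """Control and dual-shRNA knockdown matrices for two cell lines.

    Planted probes shift by ``-kd_effect_log2`` (down-regulated upon
    knockdown) under both shRNAs in both cell lines; optional
    ``n_planted_up`` probes shift up. Gaussian noise sd = ``noise_sd``.
    """
    if config.kd_effect_log2 <= 0:
        raise ValueError(
            "kd_effect_log2 must be positive (convention: planted probes go "
            "down in the knockdown arms)"
        )
    universe = gen_probe_universe(config)
    rng = config.rng(_KEY_KNOCKDOWN)
    n, reps = config.n_probes, config.n_reps
    gene_index = {g: i for i, g in enumerate(universe["genes"])}
    shift = np.zeros(n)
    for g in universe["planted_down"]:
        shift[gene_index[g]] = -config.kd_effect_log2
    for g in universe["planted_up"]:
        shift[gene_index[g]] = config.kd_effect_log2

    out: dict = {"probe_map": universe["probe_map"], "genes": universe["genes"]}
    for line in ("A", "B"):
        baseline = rng.uniform(4.0, 12.0, size=n)
        mats = {}
        for arm, arm_shift in (("control", 0.0), ("kd1", 1.0), ("kd2", 1.0)):
            mean = baseline + arm_shift * shift
            vals = mean[:, None] + rng.normal(0.0, config.noise_sd, size=(n, reps))
            mats[arm] = ExpressionMatrix(
                universe["source_probes"],
                [f"{line}_{arm}_{j + 1}" for j in range(reps)],
                vals,
                feature_kind="probe",
            )
        out[line] = mats
    out["truth"] = {
        "down": universe["planted_down"],
        "up": universe["planted_up"],
    }
    return out


def _calibrate_censor_horizon(rates: np.ndarray, target: float) -> float:
    """Find c so that uniform(0, c) censoring censors ``target`` of subjects.

    For an exponential event time with rate r and censor time U~Unif(0,c),
    P(censored) = (1 - exp(-r c)) / (r c); averaged over the subjects'
    rates, solved by bisection (decreasing in c).
    """
    def frac(c: float) -> float:
        rc = rates * c
        return float(np.mean((1.0 - np.exp(-rc)) / rc))

    lo, hi = 1e-9, 1e9
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def gen_patient_cohort(
    config: SimConfig, signature_genes: Optional[Sequence[str]] = None
) -> dict:
    """Expression cohort whose hazard depends on a planted meta-gene.

    Signature genes share a latent risk factor (loading
    ``latent_loading``); background genes are independent noise. Event
    times are exponential with a ``hazard_ratio``-fold hazard for
    patients whose meta-gene exceeds its median, censored by an
    independent uniform time calibrated to ``censor_rate``.

    The matrix is indexed by *target probe* ids (one per gene) so it can
    feed both the probe-level prognostic screen and, after collapsing,
    gene-level filters.
    """
    universe = gen_probe_universe(config)
    genes = universe["genes"]
    if signature_genes is None:
        signature_genes = universe["planted_down"]
    missing = [g for g in signature_genes if g not in set(genes)]
    if missing:
        raise ValueError(f"signature genes not in generated universe: {missing}")

    rng = config.rng(_KEY_COHORT)
    n_genes, n_pat = len(genes), config.n_patients
    lam = config.latent_loading
    z = rng.normal(size=n_pat)  # latent risk factor
    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    values = baseline[:, None] + rng.normal(size=(n_genes, n_pat))
    gene_index = {g: i for i, g in enumerate(genes)}
    sig_rows = [gene_index[g] for g in signature_genes]
    eps = rng.normal(size=(len(sig_rows), n_pat))
    values[sig_rows] = (
        np.asarray(baseline[sig_rows])[:, None]
        + lam * z[None, :]
        + np.sqrt(1.0 - lam**2) * eps
    )

    matrix = ExpressionMatrix(
        universe["target_probes"],
        [f"P{i:04d}" for i in range(n_pat)],
        values,
        feature_kind="probe",
    )

    metagene = values[sig_rows].mean(axis=0)
    high = metagene > np.median(metagene)
    rates = config.baseline_hazard * np.where(high, config.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / rates)
    if config.censor_rate == 0:
        time, event = event_time, np.ones(n_pat, dtype=bool)
    else:
        c = _calibrate_censor_horizon(rates, config.censor_rate)
        censor_time = rng.uniform(0.0, c, size=n_pat)
        event = event_time <= censor_time
        time = np.minimum(event_time, censor_time)

    er = rng.random(n_pat) < 0.7
    records = [
        SurvivalRecord(
            sample_id=f"P{i:04d}",
            time=float(time[i]),
            event=bool(event[i]),
            endpoint="DMFS",
            er_status="pos" if er[i] else "neg",
        )
        for i in range(n_pat)
    ]
    truth = {
        "metagene": dict(zip(matrix.sample_ids, metagene.tolist())),
        "high_risk": {s: bool(h) for s, h in zip(matrix.sample_ids, high)},
        "signature_genes": list(signature_genes),
    }
    return {"matrix": matrix, "records": records, "probe_map": universe["probe_map"], "truth": truth}


def gen_grade_datasets(config: SimConfig, as_matrices: bool = False) -> list[dict]:
    """Grade I vs grade III expression datasets with a planted SMD.

    Each dataset's true standardized mean difference is drawn
    Normal(planted_smd, tau^2); within-group values are unit-variance
    Gaussian; group sizes are uniform on [grade_n_min, grade_n_max].
    With ``as_matrices`` each dataset also carries a single-gene
    ExpressionMatrix plus grade labels for the end-to-end runner.
    """
    rng = config.rng(_KEY_GRADE)
    datasets: list[dict] = []
    for k in range(config.n_grade_datasets):
        true_smd = rng.normal(config.planted_smd, config.tau)
        n1 = int(rng.integers(config.grade_n_min, config.grade_n_max + 1))
        n3 = int(rng.integers(config.grade_n_min, config.grade_n_max + 1))
        vals1 = rng.normal(0.0, 1.0, size=n1)
        vals3 = rng.normal(true_smd, 1.0, size=n3)
        ds = {
            "label": f"dataset_{k + 1}",
            "values_I": vals1,
            "values_III": vals3,
            "true_smd": float(true_smd),
        }
        if as_matrices:
            sample_ids = [f"D{k + 1}_S{j}" for j in range(n1 + n3)]
            ds["matrix"] = ExpressionMatrix(
                ["GENE"], sample_ids,
                np.concatenate([vals1, vals3])[None, :],
                feature_kind="gene",
            )
            ds["grades"] = {
                s: ("I" if j < n1 else "III") for j, s in enumerate(sample_ids)
            }
        datasets.append(ds)
    return datasets


def _make_gene_models(rng: np.random.Generator, config: SimConfig) -> list[GeneModel]:
    genes: list[GeneModel] = []
    margin = 25_000
    for i in range(config.n_genes):
        chrom = f"chr{i % config.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(margin, config.chrom_len - margin))
        body = int(rng.integers(5_000, 20_000))
        # three exons spread over the gene body, transcribed away from the TSS
        e1 = int(rng.integers(200, 500))
        e2 = int(rng.integers(200, 500))
        e3 = int(rng.integers(200, 800))
        g1 = int(rng.integers(500, max(600, body // 2 - e2)))
        g2 = body - e1 - e2 - e3 - g1
        if g2 < 100:
            g2 = 100
        if strand == "+":
            starts = [tss, tss + e1 + g1, tss + e1 + g1 + e2 + g2]
            lens = [e1, e2, e3]
        else:
            end = tss
            starts = [end - e1, end - e1 - g1 - e2, end - e1 - g1 - e2 - g2 - e3]
            lens = [e1, e2, e3]
            starts, lens = starts[::-1], lens[::-1]
        exons = [
            GenomicInterval(chrom, s, s + ln, strand) for s, ln in zip(starts, lens)
        ]
        genes.append(GeneModel(f"G{i:05d}", chrom, strand, tss, exons))
    return genes


def gen_genome_peaks(config: SimConfig) -> dict:
    """Toy genome: gene models, enhancer marks, and four TF peak sets.

    A ``cobind_fraction`` of genes receive one peak from each of the four
    factors inside their -2kb/+2.5kb promoter window; all remaining peaks
    are placed uniformly at random on the genome. H3K4me1-like (mark1)
    regions are placed uniformly; an ``active_enhancer_fraction`` of them
    also receive an H3K27ac-like (mark2) region.
    """
    rng = config.rng(_KEY_GENOME)
    chrom_sizes = {f"chr{i + 1}": config.chrom_len for i in range(config.n_chroms)}
    genes = _make_gene_models(rng, config)

    n_cobind = int(round(config.cobind_fraction * config.n_genes))
    if config.peaks_per_factor < n_cobind:
        raise ValueError(
            f"peaks_per_factor ({config.peaks_per_factor}) < number of "
            f"co-bound genes ({n_cobind})"
        )
    cobind_idx = sorted(rng.choice(config.n_genes, size=n_cobind, replace=False))
    cobound_genes = [genes[i].gene_id for i in cobind_idx]

    up, down, plen = 2000, 2500, config.peak_len
    # Co-bound sites: one shared summit per gene inside its promoter window;
    # each factor's peak is centered on the summit with a small jitter, so
    # coordinated binding produces genuinely intersecting peaks.
    summits: list[int] = []
    for gi in cobind_idx:
        g = genes[gi]
        if g.strand == "+":
            w_start, w_end = g.tss - up, g.tss + down
        else:
            w_start, w_end = g.tss - down, g.tss + up
        w_start = max(0, w_start) + plen
        w_end = min(chrom_sizes[g.chrom], w_end) - plen
        summits.append(int(rng.integers(w_start, w_end)))

    peaksets: list[PeakSet] = []
    for tf in TF_NAMES:
        intervals: list[GenomicInterval] = []
        for gi, summit in zip(cobind_idx, summits):
            g = genes[gi]
            jitter = int(rng.integers(-plen // 4, plen // 4 + 1))
            start = max(0, summit + jitter - plen // 2)
            intervals.append(
                GenomicInterval(g.chrom, start, start + plen, ".",
                                float(rng.uniform(5, 100)))
            )
        for _ in range(config.peaks_per_factor - n_cobind):
            chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
            start = int(rng.integers(0, chrom_sizes[chrom] - plen))
            intervals.append(
                GenomicInterval(chrom, start, start + plen, ".",
                                float(rng.uniform(5, 100)))
            )
        peaksets.append(PeakSet(tf, intervals))

    mark1_ivs: list[GenomicInterval] = []
    mark2_ivs: list[GenomicInterval] = []
    for j in range(config.n_enhancers):
        chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
        length = int(rng.integers(800, 2000))
        start = int(rng.integers(0, config.chrom_len - length))
        mark1_ivs.append(GenomicInterval(chrom, start, start + length))
        if rng.random() < config.active_enhancer_fraction:
            jitter = int(rng.integers(-200, 200))
            s2 = max(0, start + jitter)
            mark2_ivs.append(
                GenomicInterval(chrom, s2, min(config.chrom_len, s2 + length))
            )
    return {
        "chrom_sizes": chrom_sizes,
        "genes": genes,
        "peaksets": peaksets,
        "mark1": PeakSet("H3K4me1", mark1_ivs),
        "mark2": PeakSet("H3K27ac", mark2_ivs),
        "truth": {"cobound_genes": cobound_genes},
    }


def gen_fpkm_knockdown(config: SimConfig) -> dict:
    """8 control vs 8 knockdown FPKM samples with planted up/down genes.

    FPKM values are log-normal: Gaussian on the log2 scale (sd
    ``de_noise_sd``) around per-gene baselines, exponentiated. Planted
    genes shift by +/- ``de_effect_log2`` in the knockdown arm.
    """
    rng = config.rng(_KEY_FPKM)
    n = config.n_fpkm_genes
    if config.n_de_up + config.n_de_down >= n:
        raise ValueError("too many planted DE genes")
    genes = [f"R{i:05d}" for i in range(n)]
    de_idx = rng.choice(n, size=config.n_de_up + config.n_de_down, replace=False)
    up_idx = de_idx[: config.n_de_up]
    down_idx = de_idx[config.n_de_up:]
    shift = np.zeros(n)
    shift[up_idx] = config.de_effect_log2
    shift[down_idx] = -config.de_effect_log2

    baseline = rng.uniform(3.0, 9.0, size=n)
    n_ctrl = n_kd = 8
    # a fraction of non-planted genes is stably expressed: they should fall
    # to the variation filter rather than reach the t-test
    sd = np.full(n, config.de_noise_sd)
    stable = rng.random(n) < config.low_var_fraction
    stable[de_idx] = False
    sd[stable] = config.low_var_sd
    log2_ctrl = baseline[:, None] + sd[:, None] * rng.normal(size=(n, n_ctrl))
    log2_kd = (baseline + shift)[:, None] + sd[:, None] * rng.normal(size=(n, n_kd))
    values = np.power(2.0, np.hstack([log2_ctrl, log2_kd]))
    tf_cycle = [tf for tf in TF_NAMES for _ in range(2)]
    sample_ids = [f"ctrl_{j + 1}" for j in range(n_ctrl)] + [
        f"kd_{tf}_{j % 2 + 1}" for j, tf in enumerate(tf_cycle)
    ]
    labels = {s: ("control" if s.startswith("ctrl") else "knockdown") for s in sample_ids}
    matrix = ExpressionMatrix(genes, sample_ids, values, feature_kind="gene")
    truth = {
        "up": sorted(genes[i] for i in up_idx),
        "down": sorted(genes[i] for i in down_idx),
    }
    return {"matrix": matrix, "labels": labels, "truth": truth}
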