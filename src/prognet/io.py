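"""Readers and writers for the pipeline's external TSV/BED formats.

Every writer emits a ``#``-prefixed provenance line (tool version and,
when available, the generating seed); every reader skips such lines.
All coordinates are converted to 0-based half-open on load.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    PeakSet,
    ProbeMap,
    SurvivalRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_VERSION = "0.1.0"


def _provenance(seed: Optional[int] = None) -> str:
    line = f"# prognet {_VERSION}"
    if seed is not None:
        line += f" seed={seed}"
    return line


def _read_tsv(path: PathLike, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kw)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: PathLike, feature_kind: str = "probe", allow_na: bool = False
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature ids, header = samples).

    With ``allow_na`` missing cells are mean-imputed per feature and the
    imputation count is logged; otherwise any missing value is an error.
    """
    # pandas mangles duplicate header names, so check the raw header first
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            header = line.rstrip("\n").split("\t")[1:]
            break
        else:
            raise ValidationError(f"{path}: empty file")
    dup = sorted({h for h in header if header.count(h) > 1})
    if dup:
        raise ValidationError(f"{path}: duplicate sample ids in header: {dup}")

    df = pd.read_csv(
        path, sep="\t", comment="#", index_col=0, float_precision="round_trip"
    )
    features = [str(i) for i in df.index]
    samples = [str(c) for c in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        # locate the first offending cell for the error message
        for i, fid in enumerate(features):
            for j, sid in enumerate(samples):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric cell at feature {fid!r}, sample {sid!r}: "
                        f"{df.iat[i, j]!r}"
                    ) from exc
        raise
    if np.isnan(values).any():
        if not allow_na:
            n = int(np.isnan(values).sum())
            raise ValidationError(
                f"{n} missing expression values in {path}; pass allow_na=True "
                "to mean-impute per feature"
            )
        n_imputed = int(np.isnan(values).sum())
        row_means = np.nanmean(values, axis=1, keepdims=True)
        values = np.where(np.isnan(values), row_means, values)
        logger.info("mean-imputed %d missing values in %s", n_imputed, path)
    return ExpressionMatrix(features, samples, values, feature_kind)


def write_expression_matrix(
    m: ExpressionMatrix, path: PathLike, seed: Optional[int] = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance(seed) + "\n")
        fh.write("feature_id\t" + "\t".join(m.sample_ids) + "\n")
        for fid, row in zip(m.feature_ids, m.values):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

def read_bed(
    path: PathLike,
    factor_name: str,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> PeakSet:
    """Read BED3/BED6/narrowPeak into a :class:`PeakSet`.

    narrowPeak signalValue (column 7) is kept as the interval score;
    for BED6 the score column (5) is used. Chromosome names are checked
    against ``chrom_sizes`` when supplied.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = cols[0], cols[1], cols[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: end ({end}) <= start ({start})"
                )
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise ValidationError(
                        f"{path}:{lineno}: unknown chromosome {chrom!r}"
                    )
                if end > chrom_sizes[chrom]:
                    raise ValidationError(
                        f"{path}:{lineno}: interval end {end} beyond "
                        f"{chrom} length {chrom_sizes[chrom]}"
                    )
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            score: Optional[float] = None
            if len(cols) >= 10:  # narrowPeak: signalValue is column 7 (1-based)
                score = float(cols[6])
            elif len(cols) >= 5 and cols[4] not in (".", ""):
                score = float(cols[4])
            intervals.append(
                GenomicInterval(chrom, start, end, strand, score, name)
            )
    if not intervals:
        logger.warning("empty peak file %s for factor %s", path, factor_name)
    return PeakSet(factor_name, intervals)


def write_bed(peaks: PeakSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            score = "." if iv.score is None else repr(iv.score)
            name = iv.name if iv.name is not None else peaks.factor_name
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# gene models, clinical tables, chromosome sizes, probe maps
# ---------------------------------------------------------------------------

def read_gene_models(
    path: PathLike, chrom_sizes: Optional[dict[str, int]] = None
) -> list[GeneModel]:
    """Read a gene-model TSV: gene_id, chrom, strand, tss[, exon_starts, exon_ends]."""
    df = _read_tsv(path)
    required = {"gene_id", "chrom", "strand", "tss"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"gene model table missing columns {sorted(required - set(df.columns))}"
        )
    genes: list[GeneModel] = []
    for _, row in df.iterrows():
        tss = int(row["tss"])
        chrom = row["chrom"]
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ValidationError(f"gene {row['gene_id']}: unknown chrom {chrom}")
            if not (0 <= tss < chrom_sizes[chrom]):
                raise ValidationError(
                    f"gene {row['gene_id']}: tss {tss} outside {chrom}"
                )
        exons: list[GenomicInterval] = []
        if "exon_starts" in df.columns and isinstance(row.get("exon_starts"), str):
            starts = [int(x) for x in row["exon_starts"].split(",") if x != ""]
            ends = [int(x) for x in row["exon_ends"].split(",") if x != ""]
            if len(starts) != len(ends):
                raise ValidationError(
                    f"gene {row['gene_id']}: exon_starts/exon_ends length mismatch"
                )
            exons = [
                GenomicInterval(chrom, s, e, row["strand"])
                for s, e in zip(starts, ends)
            ]
        genes.append(GeneModel(row["gene_id"], chrom, row["strand"], tss, exons))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance() + "\n")
        fh.write("gene_id\tchrom\tstrand\ttss\texon_starts\texon_ends\n")
        for g in genes:
            starts = ",".join(str(e.start) for e in g.exons)
            ends = ",".join(str(e.end) for e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{starts}\t{ends}\n")


_TRUTHY = {"1", "true", "True", "TRUE", "yes"}
_FALSY = {"0", "false", "False", "FALSE", "no"}


def read_clinical(path: PathLike, time_unit: str = "months") -> list[SurvivalRecord]:
    """Read a clinical TSV (sample_id, time, event, endpoint[, er_status, grade]).

    ``time_unit`` may be 'months' or 'years'; years are converted to months.
    """
    if time_unit not in ("months", "years"):
        raise ValidationError(f"unknown time unit {time_unit!r}")
    df = _read_tsv(path)
    required = {"sample_id", "time", "event", "endpoint"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"clinical table missing columns {sorted(required - set(df.columns))}"
        )
    factor = 12.0 if time_unit == "years" else 1.0
    records: list[SurvivalRecord] = []
    for _, row in df.iterrows():
        ev = row["event"]
        if pd.isna(ev):
            raise ValidationError(f"sample {row['sample_id']}: missing event flag")
        if ev in _TRUTHY:
            event = True
        elif ev in _FALSY:
            event = False
        else:
            raise ValidationError(f"sample {row['sample_id']}: bad event flag {ev!r}")
        er = row.get("er_status")
        grade = row.get("grade")
        records.append(
            SurvivalRecord(
                sample_id=row["sample_id"],
                time=float(row["time"]) * factor,
                event=event,
                endpoint=row["endpoint"],
                er_status=None if pd.isna(er) else er,
                grade=None if pd.isna(grade) else grade,
            )
        )
    return records


def write_clinical(
    records: Sequence[SurvivalRecord], path: PathLike, seed: Optional[int] = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(seed) + "\n")
        fh.write("sample_id\ttime\tevent\tendpoint\ter_status\tgrade\n")
        for r in records:
            er = r.er_status if r.er_status is not None else "NA"
            gr = r.grade if r.grade is not None else "NA"
            fh.write(
                f"{r.sample_id}\t{repr(float(r.time))}\t{int(r.event)}\t{r.endpoint}\t{er}\t{gr}\n"
            )


def read_chrom_sizes(path: PathLike) -> dict[str, int]:
    """Read a two-column chrom/length TSV into an ordered dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: need chrom and length")
            chrom, length = parts[0], int(parts[1])
            if length <= 0:
                raise ValidationError(f"{path}:{lineno}: non-positive length")
            if chrom in sizes:
                raise ValidationError(f"{path}:{lineno}: duplicate chrom {chrom}")
            sizes[chrom] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_probe_map(path: PathLike) -> ProbeMap:
    df = _read_tsv(path)
    required = {"source_probe_id", "gene_id", "target_probe_id"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"probe map missing columns {sorted(required - set(df.columns))}"
        )
    return ProbeMap(
        [
            (r["source_probe_id"], r["gene_id"], r["target_probe_id"])
            for _, r in df.iterrows()
        ]
    )


def write_probe_map(pmap: ProbeMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance() + "\n")
        fh.write("source_probe_id\tgene_id\ttarget_probe_id\n")
        for src, gene, tgt in pmap.rows:
            fh.write(f"{src}\t{gene}\t{tgt}\n")


def write_table(df: pd.DataFrame, path: PathLike, seed: Optional[int] = None) -> None:
    """Write a result DataFrame as TSV with a provenance header line."""
    with open(path, "w") as fh:
        fh.write(_provenance(seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)
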