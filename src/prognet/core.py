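"""Core domain containers shared across the pipeline.

All genomic coordinates are 0-based half-open ``[start, end)`` (BED
convention). Expression values are log2-scale unless a function states
otherwise. Survival times are in months.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SurvivalRecord",
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "ProbeMap",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class ExpressionMatrix:
    """Features x samples matrix of (log2) expression values.

    Parameters
    ----------
    feature_ids : unique, ordered feature (probe or gene) identifiers.
    sample_ids : unique, ordered sample identifiers.
    values : 2-D float array, shape ``(len(feature_ids), len(sample_ids))``.
    feature_kind : ``"probe"`` or ``"gene"``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    feature_kind: str = "probe"

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_kind not in ("probe", "gene"):
            raise ValidationError(
                f"feature_kind must be 'probe' or 'gene', got {self.feature_kind!r}"
            )
        dup_f = _find_duplicates(self.feature_ids)
        if dup_f:
            raise ValidationError(f"duplicate feature ids: {dup_f}")
        dup_s = _find_duplicates(self.sample_ids)
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {dup_s}")
        if self.values.ndim != 2 or self.values.shape != (
            len(self.feature_ids),
            len(self.sample_ids),
        ):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.feature_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values (use allow_na loaders)")

    # -- convenience ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_index()[feature_id]]

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        idx = self.feature_index()
        keep = [str(i) for i in ids]
        missing = [i for i in keep if i not in idx]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:10]}")
        rows = [idx[i] for i in keep]
        return ExpressionMatrix(
            keep, list(self.sample_ids), self.values[rows], self.feature_kind
        )

    def subset_samples(self, ids: Iterable[str]) -> "ExpressionMatrix":
        sidx = {s: j for j, s in enumerate(self.sample_ids)}
        keep = [str(i) for i in ids]
        missing = [i for i in keep if i not in sidx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        cols = [sidx[i] for i in keep]
        return ExpressionMatrix(
            list(self.feature_ids), keep, self.values[:, cols], self.feature_kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_kind: str = "probe") -> "ExpressionMatrix":
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
            feature_kind,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and self.feature_kind == other.feature_kind
            and np.array_equal(self.values, other.values)
        )


_ENDPOINTS = ("DMFS", "RFS")
_ER = ("pos", "neg")
_GRADES = ("I", "II", "III")


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's time-to-event record.

    ``time`` is follow-up in months; ``event`` is True if the endpoint
    (distant metastasis or relapse) was observed, False if censored.
    """

    sample_id: str
    time: float
    event: bool
    endpoint: str = "DMFS"
    er_status: Optional[str] = None
    grade: Optional[str] = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(
                f"negative survival time {self.time} for {self.sample_id}"
            )
        if self.endpoint not in _ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if self.er_status is not None and self.er_status not in _ER:
            raise ValidationError(f"unknown er_status {self.er_status!r}")
        if self.grade is not None and self.grade not in _GRADES:
            raise ValidationError(f"unknown grade {self.grade!r}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap


@dataclass
class PeakSet:
    """A named transcription factor's (or histone mark's) peak intervals."""

    factor_name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.factor_name:
            raise ValidationError("factor_name must be non-empty")

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Intervals grouped by chromosome as (n, 2) start/end arrays."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {
            c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2)
            for c, v in out.items()
        }


@dataclass
class GeneModel:
    """Gene with TSS and optional exon structure; strand is + or -."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: negative tss")
        if self.exons:
            exs = sorted(self.exons, key=lambda e: e.start)
            for a, b in zip(exs, exs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"gene {self.gene_id}: overlapping exons "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
            expected = exs[0].start if self.strand == "+" else exs[-1].end
            if self.tss != expected:
                raise ValidationError(
                    f"gene {self.gene_id}: tss {self.tss} inconsistent with exons "
                    f"(expected {expected} on strand {self.strand})"
                )
            self.exons = exs

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent covered by the exon structure (or tss alone)."""
        if not self.exons:
            return (self.tss, self.tss + 1)
        return (self.exons[0].start, self.exons[-1].end)


_SUFFIX_CLASSES = ("_s_at", "_x_at", "_at")  # order matters for classification


def probe_suffix_class(probe_id: str) -> str:
    """Classify an array probe id by its suffix: '_s_at', '_x_at' or '_at'.

    The longer suffixes are checked first since every class ends in '_at'.
    """
    for suf in _SUFFIX_CLASSES:
        if probe_id.endswith(suf):
            return suf
    raise ValidationError(f"probe id {probe_id!r} has no recognized suffix")


@dataclass
class ProbeMap:
    """Mapping from platform-A probes to platform-B probes and gene ids.

    Rows are (source_probe_id, gene_id, target_probe_id); every target
    probe id must carry an '_at' / '_s_at' / '_x_at' suffix.
    """

    rows: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for src, gene, tgt in self.rows:
            probe_suffix_class(tgt)  # raises on bad suffix
            key = (src, tgt)
            if key in seen:
                raise ValidationError(f"duplicate probe-map pair {key}")
            seen.add(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["source_probe_id", "gene_id", "target_probe_id"]
        )

    def gene_of_target(self) -> dict[str, str]:
        return {tgt: gene for _, gene, tgt in self.rows}

    def targets_of_source(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for src, _, tgt in self.rows:
            out.setdefault(src, []).append(tgt)
        return out

    def targets_of_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for _, gene, tgt in self.rows:
            out.setdefault(gene, []).append(tgt)
        return out
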