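"""Core genomic data types shared by every pipeline stage.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
Variant positions from 1-based sources are converted at the reader boundary,
never downstream. Chromosome names are compared as exact strings; no
``chr``-prefix normalization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}
CONSEQUENCE_CLASSES = {"protein_altering", "synonymous", "noncoding"}


class ValidationError(ValueError):
    """Raised when a record or file violates a documented invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """Point containment under the half-open convention: s <= pos < e."""
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 shared base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class VariantRecord:
    """One catalogued risk variant.

    ``pos`` is 0-based. ``locus_id`` indexes the GWAS risk locus (1-34 in the
    AMD catalog). ``am_score`` is the AlphaMissense pathogenicity score for
    missense variants; ``r2_to_index`` is the maximal LD R-squared to an index
    variant assigned during catalog expansion.
    """

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    locus_id: Optional[int] = None
    is_index: bool = False
    consequence: str = "noncoding"
    am_score: Optional[float] = None
    r2_to_index: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"{self.rsid}: ref and alt alleles must differ"
            )
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValidationError(
                f"{self.rsid}: consequence {self.consequence!r} not in "
                f"{sorted(CONSEQUENCE_CLASSES)}"
            )
        if self.am_score is not None and not (0.0 <= self.am_score <= 1.0):
            raise ValidationError(
                f"{self.rsid}: am_score must be in [0,1], got {self.am_score}"
            )
        if self.r2_to_index is not None and not (0.0 <= self.r2_to_index <= 1.0):
            raise ValidationError(
                f"{self.rsid}: r2_to_index must be in [0,1], got "
                f"{self.r2_to_index}"
            )

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    def allele_key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


class PeakSet:
    """Named collection of intervals for one cell type or tissue.

    Intervals are kept sorted by (chrom, start); zero-length intervals are
    rejected at construction.
    """

    def __init__(self, label: str, intervals: Iterable[GenomicInterval]):
        self.label = label
        self.intervals: List[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PeakSet)
            and self.label == other.label
            and self.intervals == other.intervals
        )

    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclass(frozen=True)
class GeneModel:
    """Gene identified by its TSS; strand orients the promoter window."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(
                f"{self.gene_id}: strand must be '+' or '-', got "
                f"{self.strand!r}"
            )
        if self.tss < 0:
            raise ValidationError(f"{self.gene_id}: tss must be >= 0")


@dataclass(frozen=True)
class Loop:
    """One chromatin loop; anchors stored in canonical (chrom, start) order."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    score: Optional[float] = None

    @staticmethod
    def make(a: GenomicInterval, b: GenomicInterval, score=None) -> "Loop":
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            a, b = b, a
        return Loop(a, b, score)


class LoopSet:
    """Deduplicated, canonically ordered loop collection."""

    def __init__(self, loops: Iterable[Loop]):
        seen = {}
        for lp in loops:
            canon = Loop.make(lp.anchor1, lp.anchor2, lp.score)
            key = (canon.anchor1, canon.anchor2)
            if key not in seen:
                seen[key] = canon
        self.loops: List[Loop] = sorted(
            seen.values(),
            key=lambda lp: (
                lp.anchor1.chrom,
                lp.anchor1.start,
                lp.anchor2.chrom,
                lp.anchor2.start,
            ),
        )

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)


class ContactMap:
    """Dense per-chromosome contact-frequency matrices at fixed resolution.

    Desk-scale genomes only: matrices are stored dense. Matrices must be
    square, symmetric and nonnegative; ``symmetrize`` averages (i,j)/(j,i)
    for inputs that are asymmetric by small amounts.
    """

    def __init__(self, resolution_bp: int, matrices: Dict[str, np.ndarray]):
        if resolution_bp <= 0:
            raise ValidationError("resolution_bp must be positive")
        self.resolution_bp = int(resolution_bp)
        self.matrices: Dict[str, np.ndarray] = {}
        for chrom, mat in matrices.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise ValidationError(
                    f"{chrom}: contact matrix must be square, got {mat.shape}"
                )
            if (mat < 0).any():
                raise ValidationError(f"{chrom}: negative contact values")
            if not np.allclose(mat, mat.T):
                raise ValidationError(f"{chrom}: contact matrix not symmetric")
            self.matrices[chrom] = mat

    @staticmethod
    def symmetrize(mat: np.ndarray) -> np.ndarray:
        mat = np.asarray(mat, dtype=float)
        return (mat + mat.T) / 2.0

    def bin_of(self, pos: int) -> int:
        return pos // self.resolution_bp

    def n_bins(self, chrom: str) -> int:
        return self.matrices[chrom].shape[0]

    def contact(self, chrom: str, bin_i: int, bin_j: int) -> Optional[float]:
        """Contact frequency between two bins; None if outside the map."""
        mat = self.matrices.get(chrom)
        if mat is None:
            return None
        n = mat.shape[0]
        if not (0 <= bin_i < n and 0 <= bin_j < n):
            return None
        return float(mat[bin_i, bin_j])

    def expected_at_distance(self, chrom: str, dist_bins: int) -> float:
        """Mean observed contact at a bin distance (distance-decay profile).

        Used as a fallback for element/TSS pairs whose bins fall outside the
        map: the expected contact is read off the map's own decay curve.
        """
        mat = self.matrices[chrom]
        n = mat.shape[0]
        d = min(abs(int(dist_bins)), n - 1)
        diag = np.diagonal(mat, offset=d)
        return float(diag.mean()) if diag.size else 0.0


class FeatureMatrix:
    """Nonnegative feature x sample matrix (accessibility or expression).

    Thin wrapper over a pandas DataFrame; ``kind`` records the assay.
    """

    KINDS = {"accessibility", "expression"}

    def __init__(self, values: pd.DataFrame, kind: str):
        if kind not in self.KINDS:
            raise ValidationError(f"kind must be one of {self.KINDS}")
        values = values.astype(float)
        if (values.to_numpy() < 0).any():
            raise ValidationError("FeatureMatrix values must be nonnegative")
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValidationError("duplicate feature or sample IDs")
        self.values = values
        self.kind = kind

    @property
    def feature_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def subset_features(self, ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[list(ids)], self.kind)
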