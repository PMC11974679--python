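"""Readers and writers for the plain-text formats the pipeline exchanges.

BED and BEDPE follow the usual 0-based half-open convention. Variant, gene,
eQTL and prediction tables are TSV with a header. Contact maps and feature
matrices are whitespace-delimited dense matrices with row/column labels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .core import (
    CONSEQUENCE_CLASSES,
    ContactMap,
    FeatureMatrix,
    GeneModel,
    GenomicInterval,
    Loop,
    LoopSet,
    PeakSet,
    ValidationError,
    VariantRecord,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_coord(token: str, path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: non-integer coordinate {token!r}"
        ) from None


def read_bed(path: PathLike, label: Optional[str] = None) -> PeakSet:
    """Read a BED3+ file into a sorted PeakSet."""
    intervals = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 columns")
        chrom = fields[0]
        start = _parse_coord(fields[1], path, lineno)
        end = _parse_coord(fields[2], path, lineno)
        if end <= start or start < 0:
            raise ParseError(
                f"{path}:{lineno}: invalid interval [{start}, {end})"
            )
        strand = fields[5] if len(fields) >= 6 and fields[5] in "+-." else "."
        intervals.append(GenomicInterval(chrom, start, end, strand))
    return PeakSet(label or Path(path).stem, intervals)


def write_bed(peakset: PeakSet, path: PathLike) -> None:
    """Write a PeakSet as BED3 (sorted, tab-separated)."""
    with open(path, "w") as fh:
        for iv in peakset:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedpe(path: PathLike) -> LoopSet:
    """Read a BEDPE file; anchors canonically ordered, loops deduplicated."""
    loops = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected >=6 columns")
        coords = [
            _parse_coord(fields[i], path, lineno) for i in (1, 2, 4, 5)
        ]
        try:
            a = GenomicInterval(fields[0], coords[0], coords[1])
            b = GenomicInterval(fields[3], coords[2], coords[3])
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        score = None
        if len(fields) >= 8 and fields[7] not in {".", ""}:
            try:
                score = float(fields[7])
            except ValueError:
                score = None
        loops.append(Loop.make(a, b, score))
    return LoopSet(loops)


def write_bedpe(loopset: LoopSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for lp in loopset:
            a, b = lp.anchor1, lp.anchor2
            score = "." if lp.score is None else repr(lp.score)
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t"
                f"{b.chrom}\t{b.start}\t{b.end}\tloop\t{score}\n"
            )


_VARIANT_REQUIRED = ["rsid", "chrom", "pos", "ref_allele", "alt_allele"]
_VARIANT_OPTIONAL = [
    "locus_id",
    "is_index",
    "consequence",
    "am_score",
    "r2_to_index",
]


def read_variant_table(path: PathLike, one_based: bool = False) -> List[VariantRecord]:
    """Read a TSV variant table into VariantRecords.

    ``one_based=True`` converts positions to the internal 0-based convention
    at this boundary.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str})
    missing = [c for c in _VARIANT_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    records = []
    for _, row in df.iterrows():
        consequence = row.get("consequence", "noncoding")
        if pd.isna(consequence):
            consequence = "noncoding"
        if consequence not in CONSEQUENCE_CLASSES:
            raise ValidationError(
                f"{path}: rsid {row['rsid']}: unknown consequence "
                f"{consequence!r}; allowed: {sorted(CONSEQUENCE_CLASSES)}"
            )

        def _opt(name, cast):
            if name not in df.columns or pd.isna(row[name]):
                return None
            return cast(row[name])

        records.append(
            VariantRecord(
                rsid=str(row["rsid"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]) - (1 if one_based else 0),
                ref_allele=str(row["ref_allele"]),
                alt_allele=str(row["alt_allele"]),
                locus_id=_opt("locus_id", int),
                is_index=bool(_opt("is_index", int) or 0),
                consequence=str(consequence),
                am_score=_opt("am_score", float),
                r2_to_index=_opt("r2_to_index", float),
            )
        )
    return records


def write_variant_table(variants: List[VariantRecord], path: PathLike) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "rsid": v.rsid,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref_allele": v.ref_allele,
                "alt_allele": v.alt_allele,
                "locus_id": v.locus_id,
                "is_index": int(v.is_index),
                "consequence": v.consequence,
                "am_score": v.am_score,
                "r2_to_index": v.r2_to_index,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models(path: PathLike) -> List[GeneModel]:
    """TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    for col in ("gene_id", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return [
        GeneModel(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def write_gene_models(genes: List[GeneModel], path: PathLike) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss, "strand": g.strand}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_contact_map(path: PathLike, resolution_bp: int) -> ContactMap:
    """Read a dense contact matrix TSV.

    Row/column labels are ``chrom:bin_index``. Multiple chromosomes may share
    one file as block-diagonal blocks; cross-chromosome entries must be zero.
    Mildly asymmetric blocks are symmetrized by averaging (i,j) and (j,i).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ParseError(
            f"{path}: contact matrix must be square, got {df.shape}"
        )
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column labels differ")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError(f"{path}: negative contact values")
    labels = [str(x) for x in df.index]
    chrom_of, bin_of = [], []
    for lab in labels:
        chrom, _, b = lab.rpartition(":")
        if not chrom:
            raise ParseError(f"{path}: label {lab!r} is not 'chrom:bin'")
        chrom_of.append(chrom)
        bin_of.append(int(b))
    matrices: Dict[str, np.ndarray] = {}
    chroms = sorted(set(chrom_of))
    idx = {c: [i for i, cc in enumerate(chrom_of) if cc == c] for c in chroms}
    for c in chroms:
        rows = idx[c]
        bins = [bin_of[i] for i in rows]
        if bins != list(range(len(bins))):
            raise ParseError(f"{path}: {c}: bins must be 0..n-1 in order")
        block = values[np.ix_(rows, rows)]
        matrices[c] = ContactMap.symmetrize(block)
        others = [i for i in range(len(labels)) if chrom_of[i] != c]
        if others and values[np.ix_(rows, others)].any():
            raise ValidationError(
                f"{path}: nonzero cross-chromosome contacts not supported"
            )
    return ContactMap(resolution_bp, matrices)


def write_contact_map(cmap: ContactMap, path: PathLike) -> None:
    labels, blocks = [], []
    chroms = sorted(cmap.matrices)
    for c in chroms:
        n = cmap.matrices[c].shape[0]
        labels.extend(f"{c}:{i}" for i in range(n))
    total = len(labels)
    full = np.zeros((total, total))
    offset = 0
    for c in chroms:
        mat = cmap.matrices[c]
        n = mat.shape[0]
        full[offset : offset + n, offset : offset + n] = mat
        offset += n
    pd.DataFrame(full, index=labels, columns=labels).to_csv(path, sep="\t")


def read_feature_matrix(path: PathLike, kind: str) -> FeatureMatrix:
    """Whitespace-delimited matrix with row labels and a header of sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureMatrix(df, kind)


def write_feature_matrix(fm: FeatureMatrix, path: PathLike) -> None:
    fm.values.to_csv(path, sep="\t")


def read_eqtl_table(path: PathLike) -> pd.DataFrame:
    """TSV with columns rsid, gene_id, tissue_region, fdr."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "gene_id": str})
    for col in ("rsid", "tissue_region", "fdr"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    bad = set(df["tissue_region"]) - {"macular", "non_macular"}
    if bad:
        raise ValidationError(f"{path}: unknown tissue_region values {bad}")
    return df


def read_prediction_table(path: PathLike) -> pd.DataFrame:
    """TSV with columns rsid, cell_type, fold, ref_count, alt_count."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "cell_type": str})
    for col in ("rsid", "cell_type", "fold", "ref_count", "alt_count"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df


def write_json(obj, path: PathLike) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
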