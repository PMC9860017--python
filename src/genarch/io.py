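"""Readers and writers for every on-disk format the pipeline touches.

Formats (all plain text):

* summary statistics — TSV with columns SNP, CHR, BP, A1, A2, Z, N
  (case-insensitive header);
* annotations — TSV with SNP, CHR, BP then one column per annotation;
* intervals — BED3+ (0-based half-open);
* LD matrices — square TSV with SNP labels as header and first column;
* rare-variant cohorts — VCF 4.x with GT fields plus a phenotype/covariate
  TSV keyed on sample ID.

Numeric fields are written with 17 significant digits so that every
reader/writer pair round-trips losslessly. Parsers reject malformed input
with a located error rather than silently coercing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pysam

from .containers import SUMSTAT_COLUMNS, AnnotationMatrix, LDMatrix, SumStats
from .errors import FormatError, IntegrityError

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# ---------------------------------------------------------------------------
# summary statistics


def read_sumstats(path) -> SumStats:
    """Read LDSC-dialect summary statistics.

    Rows whose Z or N field is not numeric are dropped and counted in
    ``SumStats.n_dropped``; duplicate variant identifiers are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    upper = {c.upper(): c for c in df.columns}
    missing = [c for c in SUMSTAT_COLUMNS if c not in upper]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    df = df.rename(columns={upper[c]: c for c in SUMSTAT_COLUMNS})[SUMSTAT_COLUMNS]
    z = pd.to_numeric(df["Z"], errors="coerce")
    n = pd.to_numeric(df["N"], errors="coerce")
    keep = z.notna() & n.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("read_sumstats(%s): dropped %d rows with non-numeric Z/N",
                 path, n_dropped)
    df = df.loc[keep].copy()
    # python float() is correctly rounded; pandas' fast parser can be 1 ulp off
    df["Z"] = df["Z"].map(float)
    df["N"] = df["N"].map(float)
    df["BP"] = pd.to_numeric(df["BP"]).astype(int)
    return SumStats(df.reset_index(drop=True), n_dropped=n_dropped)


def write_sumstats(ss: SumStats, path) -> None:
    df = ss.table.copy()
    df["Z"] = df["Z"].map(_fmt)
    df["N"] = df["N"].map(_fmt)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations (.annot dialect)


def read_annot(path) -> AnnotationMatrix:
    df = pd.read_csv(path, sep="\t")
    for c in ("SNP", "CHR", "BP"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {c!r}")
    ann_cols = [c for c in df.columns if c not in ("SNP", "CHR", "BP")]
    if not ann_cols:
        raise FormatError(f"{path}: no annotation columns")
    return AnnotationMatrix(df[["SNP", "CHR", "BP"]], df[ann_cols].astype(float))


def write_annot(annot: AnnotationMatrix, path) -> None:
    df = pd.concat([annot.snps, annot.values.map(lambda v: _fmt(float(v)))], axis=1)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals


def read_intervals(path) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end[, name]).

    Coordinates stay 0-based half-open; output is sorted by (chrom, start,
    end). Zero-length or inverted intervals are rejected with a line number.
    """
    rows = []
    has_name = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else None
            has_name = has_name or name is not None
            rows.append((chrom, start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if not has_name:
        df = df.drop(columns=["name"])
    return df.sort_values(["chrom", "start", "end"],
                          kind="mergesort").reset_index(drop=True)


def write_intervals(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# LD matrices


def read_ld_matrix(path, snps=None) -> LDMatrix:
    """Read a labelled square correlation matrix.

    The matrix is symmetrised to (M + M')/2, the diagonal forced to 1 and
    off-diagonal entries clipped to [-1, 1] (text rounding can push them
    slightly out of range). When ``snps`` is given the labels must match.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: non-square matrix {df.shape}")
    labels = [str(c) for c in df.columns]
    if list(map(str, df.index)) != labels:
        raise FormatError(f"{path}: row and column labels differ")
    if snps is not None and list(snps) != labels:
        raise IntegrityError(f"{path}: labels do not match the given SNP list")
    return LDMatrix(labels, df.to_numpy(float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("SNP\t" + "\t".join(ld.snps) + "\n")
        for s, row in zip(ld.snps, ld.r):
            fh.write(s + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# rare-variant cohorts (VCF + phenotype table)


def write_vcf(variants: pd.DataFrame, genotypes: np.ndarray,
              samples: list[str], path) -> None:
    """Write a minimal VCF 4.2 with GT fields.

    ``variants`` needs columns chrom, pos, ref, alt and optionally id;
    ``genotypes`` is individuals x variants with values 0/1/2.
    """
    G = np.asarray(genotypes)
    if G.shape != (len(samples), len(variants)):
        raise IntegrityError("genotype matrix shape does not match samples/variants")
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        ids = variants["id"] if "id" in variants.columns else ["."] * len(variants)
        for j, (row, vid) in enumerate(zip(variants.itertuples(index=False), ids)):
            gts = "\t".join(gt_code[int(g)] for g in G[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{vid or '.'}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a VCF into (variants, genotypes individuals x variants, samples)."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, cols = [], []
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            raise FormatError(f"{path}: multi-allelic record at "
                              f"{rec.chrom}:{rec.pos} unsupported")
        rows.append((rec.chrom, rec.pos, rec.id, rec.ref, alts[0]))
        gts = [sum(a or 0 for a in rec.samples[s]["GT"]) for s in samples]
        cols.append(gts)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    G = np.asarray(cols, dtype=np.int8).T if cols else np.zeros((len(samples), 0),
                                                                dtype=np.int8)
    return variants, G, samples


def read_phenotypes(path, sample_col: str = "sample") -> pd.DataFrame:
    """Read the phenotype/covariate TSV, indexed by sample ID."""
    df = pd.read_csv(path, sep="\t")
    if sample_col not in df.columns:
        raise FormatError(f"{path}: missing sample-ID column {sample_col!r}")
    if df[sample_col].duplicated().any():
        dup = df.loc[df[sample_col].duplicated(), sample_col].iloc[0]
        raise IntegrityError(f"{path}: duplicate sample ID {dup!r}")
    return df.set_index(sample_col)


def write_phenotypes(df: pd.DataFrame, path, sample_col: str = "sample") -> None:
    df.reset_index().rename(columns={"index": sample_col}).to_csv(
        path, sep="\t", index=False)
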