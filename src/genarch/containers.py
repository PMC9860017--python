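"""In-memory containers shared across the pipeline.

All tabular data is held in pandas DataFrames with fixed column names;
the thin dataclass wrappers exist to carry invariants (unique variant keys,
symmetrised LD, annotation values in [0, 1]) and derived quantities.

Coordinate conventions: variants are 1-based (VCF style); BED intervals are
0-based half-open and are converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, IntegrityError


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: chromosome, 1-based position, ref and alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.pos < 1:
            raise ArgumentError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ArgumentError(f"ref and alt alleles are identical ({self.ref}) at "
                                f"{self.chrom}:{self.pos}")

    def __str__(self):
        return f"{self.chrom}:g.{self.pos}{self.ref}>{self.alt}"


SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N"]


@dataclass
class SumStats:
    """GWAS marginal summary statistics, one row per variant.

    ``table`` columns: SNP, CHR, BP, A1, A2, Z, N. ``n_dropped`` counts rows
    removed at read time because Z or N was not numeric.
    """

    table: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self):
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ArgumentError(f"sumstats table missing columns {missing}")
        dup = self.table["SNP"].duplicated()
        if dup.any():
            first = self.table.loc[dup, "SNP"].iloc[0]
            raise IntegrityError(f"duplicate variant key: {first!r}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self):
        return len(self.table)

    @property
    def z(self) -> np.ndarray:
        return self.table["Z"].to_numpy(float)

    @property
    def n(self) -> np.ndarray:
        return self.table["N"].to_numpy(float)

    @property
    def chi2(self) -> np.ndarray:
        """chi-square statistics, exactly z**2."""
        return self.z ** 2

    @property
    def snps(self) -> pd.Index:
        return pd.Index(self.table["SNP"])

    def reindex(self, snps) -> "SumStats":
        """Restrict/reorder to ``snps``; missing SNPs are an integrity error."""
        idx = self.table.set_index("SNP")
        missing = [s for s in snps if s not in idx.index]
        if missing:
            raise IntegrityError(f"SNPs absent from sumstats: {missing[:5]}")
        return SumStats(idx.loc[list(snps)].reset_index(), self.n_dropped)


@dataclass
class LDMatrix:
    """Symmetric SNP-by-SNP correlation matrix with a SNP label index."""

    snps: list[str]
    r: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ArgumentError(f"LD matrix must be square, got shape {r.shape}")
        if len(self.snps) != r.shape[0]:
            raise IntegrityError("LD matrix size does not match SNP list")
        r = (r + r.T) / 2.0
        off = ~np.eye(r.shape[0], dtype=bool)
        r[off] = np.clip(r[off], -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        self.r = r
        self.snps = list(self.snps)

    def __len__(self):
        return len(self.snps)

    def submatrix(self, snps) -> "LDMatrix":
        pos = {s: i for i, s in enumerate(self.snps)}
        missing = [s for s in snps if s not in pos]
        if missing:
            raise IntegrityError(f"SNPs absent from LD matrix: {missing[:5]}")
        idx = [pos[s] for s in snps]
        return LDMatrix(list(snps), self.r[np.ix_(idx, idx)])


@dataclass
class AnnotationMatrix:
    """Per-SNP annotation values a_c(k), one named column per annotation.

    ``snps`` is a DataFrame with SNP/CHR/BP; ``values`` holds the annotation
    columns (binary {0,1} or continuous in [0,1]), aligned row-wise to snps.
    """

    snps: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self):
        if len(self.snps) != len(self.values):
            raise IntegrityError("annotation values not aligned to SNP table")
        if self.values.columns.duplicated().any():
            raise ArgumentError("annotation column names must be unique")
        v = self.values.to_numpy(float)
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ArgumentError("annotation values must lie in [0, 1]")
        self.snps = self.snps.reset_index(drop=True)
        self.values = self.values.reset_index(drop=True)

    def __len__(self):
        return len(self.snps)

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def column(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy(float)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(float)

    def m_annot(self) -> pd.Series:
        """Annotation sizes M_c = sum_k a_c(k) (SNP counts for binary columns)."""
        return self.values.sum(axis=0)

    def sd(self) -> pd.Series:
        """Population standard deviation of each annotation column."""
        return self.values.std(axis=0, ddof=0)

    def is_binary(self, name: str) -> bool:
        v = self.column(name)
        return bool(np.all((v == 0) | (v == 1)))

    def subset(self, names) -> "AnnotationMatrix":
        return AnnotationMatrix(self.snps, self.values[list(names)])
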