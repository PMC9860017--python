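"""Transcriptome-wide association: weights, association, meta-analysis, PIPs.

Stages:

* cis-heritability screen — Haseman-Elston regression of expression products
  on cis-window genotype relatedness, with a permutation p-value; genes
  failing the screen are excluded from weight fitting;
* expression weights — either the single top marginal eQTL or ridge
  regression with cross-validated shrinkage;
* summary-based association — Z_twas = w'z / sqrt(w'Rw) given GWAS z-scores
  and an LD reference, invariant to rescaling of w;
* two-stage discovery/replication with Stouffer's weighted-Z meta-analysis,
  weights proportional to the effective case/control sample size
  N_eff = 4/(1/N_cases + 1/N_controls), and Bonferroni/FDR control over
  genes x tissues;
* gene-level fine-mapping — the configuration-enumeration machinery applied
  to TWAS z-scores with the predicted-expression correlation matrix in place
  of SNP LD, including the no-causal-gene configuration, yielding posterior
  inclusion probabilities (PIPs) and a 90%-credible gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, NumericError
from .finemap import compute_cpp
from .ldsc import adjust_pvalues

__all__ = [
    "estimate_cis_h2", "WeightSet", "fit_weights", "ridge_weights",
    "twas_associate", "n_eff", "stouffer_meta", "combine_stages",
    "multiple_testing", "GenePIPResult", "gene_pip",
]


# ---------------------------------------------------------------------------
# cis-heritability screen


def estimate_cis_h2(genotypes, expression, n_permutations: int = 200,
                    seed: int = 0, min_individuals: int = 50) -> tuple[float, float]:
    """Haseman-Elston estimate of cis-heritability with a permutation p.

    Regresses off-diagonal expression products y_i*y_j on the cis-window
    genotype relatedness A_ij; the p-value permutes expression labels
    (default 200 permutations, seeded). Requires >= ``min_individuals``
    individuals and >= 2 cis SNPs.
    """
    x = np.asarray(genotypes, float)
    y = np.asarray(expression, float)
    n, m = x.shape
    if n < min_individuals:
        raise ArgumentError(f"need >= {min_individuals} individuals, got {n}")
    if m < 2:
        raise ArgumentError("need >= 2 cis SNPs")
    if y.std(ddof=0) == 0:
        raise NumericError("constant expression vector")
    xs = (x - x.mean(0)) / np.where(x.std(0, ddof=0) == 0, 1.0, x.std(0, ddof=0))
    y = (y - y.mean()) / y.std(ddof=0)
    a = xs @ xs.T / m
    diag = np.diag(a).copy()
    denom = float((a**2).sum() - (diag**2).sum())

    def he(yv):
        return float((yv @ a @ yv - diag @ yv**2) / denom)

    h2 = he(y)
    if n_permutations == 0:
        return h2, float("nan")
    rng = np.random.default_rng(seed)
    exceed = sum(he(rng.permutation(y)) >= h2 for _ in range(n_permutations))
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return h2, p


# ---------------------------------------------------------------------------
# expression weights


@dataclass
class WeightSet:
    """Per-SNP expression weights for one gene in one tissue."""

    gene: str
    tissue: str
    snps: list[str]
    weights: np.ndarray
    hsq: float
    hsq_p: float
    method: str

    def __post_init__(self):
        if np.all(self.weights == 0):
            raise ArgumentError(f"all-zero weight vector for gene {self.gene}")


def ridge_weights(genotypes, expression, lam: float) -> np.ndarray:
    """Closed-form ridge solution (X'X + lam*I)^-1 X'y on standardized X."""
    x = np.asarray(genotypes, float)
    xs = (x - x.mean(0)) / np.where(x.std(0, ddof=0) == 0, 1.0, x.std(0, ddof=0))
    y = np.asarray(expression, float)
    y = y - y.mean()
    m = xs.shape[1]
    return np.linalg.solve(xs.T @ xs + lam * np.eye(m), xs.T @ y)


def fit_weights(genotypes, expression, method: str = "top_eqtl",
                lambdas=None, n_folds: int = 5, seed: int = 0,
                gene: str = "gene", tissue: str = "tissue",
                hsq: float = np.nan, hsq_p: float = np.nan,
                snps=None) -> WeightSet:
    """Fit expression weights by the chosen method.

    ``top_eqtl`` puts weight 1 on the SNP with the largest marginal chi2;
    ``ridge`` solves (X'X + lam*I)^-1 X'y with lam chosen by ``n_folds``-fold
    cross-validated mean squared error over a fixed grid (scaled by the SNP
    count). Ridge with fewer than 25 individuals falls back to top_eqtl with
    a warning.
    """
    x = np.asarray(genotypes, float)
    y = np.asarray(expression, float)
    n, m = x.shape
    snps = list(snps) if snps is not None else [f"snp{i}" for i in range(m)]
    if method == "ridge" and n < 25:
        warnings.warn("ridge cross-validation degenerate for n < 25; "
                      "falling back to top_eqtl", stacklevel=2)
        method = "top_eqtl"
    if method == "top_eqtl":
        sd = x.std(0, ddof=0)
        xs = (x - x.mean(0)) / np.where(sd == 0, 1.0, sd)
        yc = (y - y.mean()) / y.std(ddof=0)
        z = xs.T @ yc / np.sqrt(n)
        top = int(np.argmax(z**2))
        w = np.zeros(m)
        w[top] = 1.0
    elif method == "ridge":
        if lambdas is None:
            lambdas = m * np.logspace(-1.0, 2.5, 8)
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.array_split(order, n_folds)
        mse = np.zeros(len(lambdas))
        for hold in folds:
            train = np.setdiff1d(order, hold)
            for li, lam in enumerate(lambdas):
                w_tr = ridge_weights(x[train], y[train], lam)
                sd = x[train].std(0, ddof=0)
                xs_hold = (x[hold] - x[train].mean(0)) / np.where(sd == 0, 1.0, sd)
                pred = xs_hold @ w_tr
                mse[li] += float(((y[hold] - y[hold].mean() - pred) ** 2).sum())
        lam = float(lambdas[int(np.argmin(mse))])
        w = ridge_weights(x, y, lam)
    else:
        raise ArgumentError(f"unknown weight method {method!r}")
    return WeightSet(gene=gene, tissue=tissue, snps=snps, weights=w,
                     hsq=hsq, hsq_p=hsq_p, method=method)


# ---------------------------------------------------------------------------
# association statistic


def twas_associate(weights, gwas_z, ld) -> tuple[float, float]:
    """Association between predicted expression and the trait.

    Z_twas = w'z / sqrt(w'Rw); the p-value is the two-sided normal tail.
    Invariant to positive rescaling of w.
    """
    w = np.asarray(weights, float)
    z = np.asarray(gwas_z, float)
    r = ld.r if hasattr(ld, "r") else np.asarray(ld, float)
    if w.shape != z.shape or r.shape != (w.size, w.size):
        raise ArgumentError("weights, z and LD matrix sizes disagree")
    denom = float(w @ r @ w)
    if denom <= 0:
        raise NumericError("w'Rw <= 0; LD matrix not PSD on the weight support")
    zt = float(w @ z / np.sqrt(denom))
    return zt, float(2 * stats.norm.sf(abs(zt)))


# ---------------------------------------------------------------------------
# meta-analysis across stages


def n_eff(n_cases: float, n_controls: float) -> float:
    """Effective sample size 4/(1/N_cases + 1/N_controls)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ArgumentError("case/control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def stouffer_meta(z_by_stage, counts_by_stage,
                  weight_mode: str = "n_eff") -> tuple[float, float]:
    """Weighted Stouffer combination of per-stage z-scores.

    ``counts_by_stage`` is a sequence of (n_cases, n_controls) pairs; stage
    weights are proportional to N_eff (default), sqrt(N_eff) or total N.
    Z_combined = sum_s w_s z_s / sqrt(sum_s w_s^2); p is two-sided.
    """
    z = np.asarray(z_by_stage, float)
    if z.size < 2:
        raise ArgumentError("need at least 2 stages")
    if len(counts_by_stage) != z.size:
        raise ArgumentError("missing case/control counts for some stage")
    if weight_mode == "n_eff":
        w = np.array([n_eff(*c) for c in counts_by_stage])
    elif weight_mode == "sqrt_n_eff":
        w = np.sqrt([n_eff(*c) for c in counts_by_stage])
    elif weight_mode == "total_n":
        w = np.array([c[0] + c[1] for c in counts_by_stage], float)
    else:
        raise ArgumentError(f"unknown weight_mode {weight_mode!r}")
    zc = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    return zc, float(2 * stats.norm.sf(abs(zc)))


def combine_stages(results: pd.DataFrame, counts_discovery, counts_replication,
                   weight_mode: str = "n_eff") -> pd.DataFrame:
    """Two-stage TWAS table with combined Stouffer z and p per gene.

    ``results`` needs columns gene, z_discovery, z_replication.
    """
    out = results.copy()
    out["p_discovery"] = 2 * stats.norm.sf(out["z_discovery"].abs())
    out["p_replication"] = 2 * stats.norm.sf(out["z_replication"].abs())
    combined = [stouffer_meta((zd, zr), [counts_discovery, counts_replication],
                              weight_mode=weight_mode)
                for zd, zr in zip(out["z_discovery"], out["z_replication"])]
    out["z_combined"] = [c[0] for c in combined]
    out["p_combined"] = [c[1] for c in combined]
    return out


def multiple_testing(results: pd.DataFrame, n_genes: int, n_tissues: int,
                     p_column: str = "p_combined",
                     alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni (alpha / (n_genes * n_tissues)) and BH flags."""
    if n_genes < 1 or n_tissues < 1:
        raise ArgumentError("counts must be >= 1")
    out = results.copy()
    threshold = alpha / (n_genes * n_tissues)
    out["bonferroni_significant"] = out[p_column] < threshold
    out["fdr_significant"] = adjust_pvalues(out[p_column].to_numpy(), method="bh",
                                            alpha=alpha)
    return out


# ---------------------------------------------------------------------------
# gene-level fine-mapping


@dataclass
class GenePIPResult:
    """Per-gene posterior inclusion probabilities for one TWAS region."""

    region: str
    genes: list[str]
    pip: np.ndarray
    credible: np.ndarray          # 90%-credible gene set membership
    level: float


def gene_pip(z_by_gene, gene_correlation, prior_causal: float | None = None,
             ncp_scale: float = 5.2, level: float = 0.90,
             max_genes: int = 15, region: str = "region",
             genes=None) -> GenePIPResult:
    """Gene-level fine-mapping of a TWAS region.

    Applies the causal-configuration enumeration to gene-level z-scores with
    the predicted-expression correlation matrix in place of SNP LD. All
    configurations up to the region size are enumerated, including the null
    (no causal gene) one, so PIPs need not sum to >= 1. The credible gene
    set accumulates genes by descending PIP until the cumulative posterior
    reaches ``level``.
    """
    z = np.asarray(z_by_gene, float)
    g = z.size
    if g > max_genes:
        from .errors import SizeError
        raise SizeError(f"region has {g} genes > enumeration cap {max_genes}")
    # prior capped just below 1 so the null configuration keeps support
    # even in single-gene regions
    prior = prior_causal if prior_causal is not None else min(1.0 / g, 0.9)
    res = compute_cpp(z, np.asarray(gene_correlation, float), max_causal=g,
                      prior_causal=prior, ncp_scale=ncp_scale,
                      credible_level=level, max_snps=max_genes, max_k=max_genes,
                      include_null=True, region=region)
    pip = res.alpha
    order = np.argsort(-pip, kind="mergesort")
    credible = np.zeros(g, dtype=bool)
    # if the null model absorbs mass so that sum(pip) < level, every gene
    # is needed to get as close to the level as possible
    target = min(level, float(pip.sum()))
    cum = 0.0
    for i in order:
        credible[i] = True
        cum += pip[i]
        if cum >= target - 1e-12:
            break
    genes = list(genes) if genes is not None else [f"gene{i}" for i in range(g)]
    return GenePIPResult(region=region, genes=genes, pip=pip,
                         credible=credible, level=level)
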