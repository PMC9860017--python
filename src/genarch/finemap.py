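"""QTL effect-size meta-analysis, fine-mapping, and derived annotations.

Three pieces live here:

* inverse-variance fixed-effect meta-analysis of per-study QTL effect sizes,
  z_FE = sum_j w_j b_j / sqrt(sum_j w_j) with w_j = 1/se_j^2 (equivalently a
  weighted average of per-study z-scores);
* enumeration-based fine-mapping: for each causal configuration C the
  marginal z-vector is modelled as N(0, R + s^2 R_C R_C'), the posterior over
  configurations gives per-SNP causal posterior probabilities (CPP) and a
  95% credible set built at configuration level;
* annotation construction: MaxCPP (per-SNP maximum CPP over genes whose
  credible set contains the SNP, optionally restricted to a gene subset such
  as constrained genes) and binary RNA-binding-protein binding-site columns
  with flanking sequence.

The configuration likelihood uses a Woodbury low-rank update on the ridge-
regularised LD matrix, so regions up to the enumeration cap are cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.special import logsumexp

from .containers import AnnotationMatrix
from .errors import ArgumentError, NumericError, SizeError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fixed-effect meta-analysis


def fixed_effect_meta(betas, ses) -> float:
    """Inverse-variance weighted meta-analytic z-score for one variant.

    Parameters are the per-study effect sizes and their standard errors.
    With a single study this reduces to beta/se.
    """
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if betas.size == 0:
        raise ArgumentError("fixed_effect_meta requires at least one study")
    if betas.shape != ses.shape:
        raise ArgumentError("betas and ses must have the same length")
    if np.any(ses <= 0):
        raise ArgumentError("all standard errors must be > 0")
    w = 1.0 / ses**2
    return float(np.sum(w * betas) / np.sqrt(np.sum(w)))


def meta_qtl(effects: pd.DataFrame) -> pd.DataFrame:
    """Meta-analyse a per-study QTL effect table.

    ``effects`` has columns gene, SNP, beta, se (one row per study); output
    has one row per (gene, SNP) with the meta z-score.
    """
    out = (effects.groupby(["gene", "SNP"], sort=True)
           .apply(lambda g: fixed_effect_meta(g["beta"], g["se"]),
                  include_groups=False)
           .rename("z_fe").reset_index())
    return out


# ---------------------------------------------------------------------------
# configuration enumeration


def _config_log_liks(z, R, configs, ncp_scale, ridge):
    """Log-likelihood of z under N(0, A + s^2 R_C R_C') for each config.

    A = R + ridge*I; empty configs are allowed and give the null likelihood.
    """
    z = np.asarray(z, float)
    m = z.size
    A = np.asarray(R, float) + ridge * np.eye(m)
    try:
        cho = cho_factor(A, lower=True)
    except LinAlgError as exc:
        raise NumericError("LD matrix not positive definite after ridge "
                           "regularisation") from exc
    logdet_a = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    ainv_z = cho_solve(cho, z)
    base_quad = float(z @ ainv_z)
    const = -0.5 * m * np.log(2.0 * np.pi)
    lls = np.empty(len(configs))
    for i, cfg in enumerate(configs):
        if len(cfg) == 0:
            lls[i] = const - 0.5 * (logdet_a + base_quad)
            continue
        u = ncp_scale * R[:, list(cfg)]
        ainv_u = cho_solve(cho, u)
        mk = np.eye(len(cfg)) + u.T @ ainv_u
        sign, logdet_m = np.linalg.slogdet(mk)
        if sign <= 0:
            raise NumericError("Woodbury capacitance not positive definite")
        w = u.T @ ainv_z
        quad = base_quad - float(w @ np.linalg.solve(mk, w))
        lls[i] = const - 0.5 * (logdet_a + logdet_m + quad)
    return lls


@dataclass
class FineMapResult:
    """Per-SNP causal posteriors for one region/gene."""

    region: str
    snps: list[str]
    alpha: np.ndarray            # per-SNP CPP
    theta: np.ndarray            # credible-set membership flags {0,1}
    level: float
    max_causal: int
    config_table: pd.DataFrame   # columns: config (tuple of SNP indices), posterior

    def cpp(self, snp: str) -> float:
        return float(self.alpha[self.snps.index(snp)])


def credible_set(config_table: pd.DataFrame, n_snps: int,
                 level: float = 0.95) -> np.ndarray:
    """Configuration-level credible set.

    Configurations are sorted by posterior descending (ties broken by
    ascending SNP-index order) and accumulated until the cumulative
    posterior reaches ``level``; every SNP appearing in a retained
    configuration gets theta = 1.
    """
    posts = config_table["posterior"].to_numpy(float)
    total = posts.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ArgumentError(f"config posteriors must sum to 1 (got {total:.6g})")
    order = sorted(range(len(posts)),
                   key=lambda i: (-posts[i], tuple(config_table["config"].iloc[i])))
    theta = np.zeros(n_snps, dtype=int)
    cum = 0.0
    for i in order:
        for j in config_table["config"].iloc[i]:
            theta[j] = 1
        cum += posts[i]
        if cum >= level - 1e-12:
            break
    return theta


def compute_cpp(z, R, max_causal: int = 1, prior_causal=None,
                ncp_scale: float = 5.2, credible_level: float = 0.95,
                ridge: float = 1e-4, snps=None, region: str = "region",
                max_snps: int = 50, max_k: int = 3,
                include_null: bool = False) -> FineMapResult:
    """Enumerate causal configurations and return per-SNP CPPs.

    ``prior_causal`` is the per-SNP prior used per configuration slot
    (default 1/m); the prior of a multi-SNP configuration is the product of
    its per-SNP priors. When ``include_null`` is set the empty configuration
    is enumerated too with prior prod_j (1 - prior_j) (used by gene-level
    fine-mapping, where PIPs need not sum to 1).
    """
    z = np.asarray(z, float)
    m = z.size
    R = np.asarray(R, float)
    if R.shape != (m, m):
        raise ArgumentError(f"LD matrix shape {R.shape} does not match {m} SNPs")
    if m > max_snps or max_causal > max_k:
        raise SizeError(
            f"enumeration cap exceeded (m={m} > {max_snps} or K={max_causal} > "
            f"{max_k}); shrink the region or the maximum causal count")
    if prior_causal is None:
        prior = np.full(m, 1.0 / m)
    else:
        prior = np.broadcast_to(np.asarray(prior_causal, float), (m,)).copy()
    if np.any(prior <= 0) or np.any(prior > 1):
        raise ArgumentError("per-SNP priors must lie in (0, 1]")
    if include_null and np.any(prior >= 1):
        raise ArgumentError("per-SNP priors must be < 1 when the null "
                            "configuration is included")

    configs = []
    if include_null:
        configs.append(())
    for k in range(1, max_causal + 1):
        configs.extend(combinations(range(m), k))

    logp = np.log(prior)
    log1mp = np.log1p(-prior)
    if include_null:
        # Bernoulli inclusion prior: prod_in p_j * prod_out (1-p_j)
        log_prior = np.array([logp[list(c)].sum() + log1mp.sum()
                              - log1mp[list(c)].sum() for c in configs])
    else:
        log_prior = np.array([logp[list(c)].sum() for c in configs])

    lls = _config_log_liks(z, R, configs, ncp_scale, ridge)
    log_post = lls + log_prior
    log_post -= logsumexp(log_post)
    posts = np.exp(log_post)

    alpha = np.zeros(m)
    for cfg, p in zip(configs, posts):
        for j in cfg:
            alpha[j] += p
    alpha = np.clip(alpha, 0.0, 1.0)

    table = pd.DataFrame({"config": configs, "posterior": posts})
    theta = credible_set(table, m, level=credible_level)
    snps = list(snps) if snps is not None else [f"snp{i}" for i in range(m)]
    return FineMapResult(region=region, snps=snps, alpha=alpha, theta=theta,
                         level=credible_level, max_causal=max_causal,
                         config_table=table)


# ---------------------------------------------------------------------------
# annotations


def max_cpp_annotation(finemap_results, snp_index, gene_subset=None) -> np.ndarray:
    """MaxCPP column: a_j = max over qualifying genes of CPP, 0 if none.

    ``finemap_results`` maps gene ID -> :class:`FineMapResult`. A gene
    qualifies for SNP j when j is in its credible set (theta = 1). When
    ``gene_subset`` is given, only those genes are considered; subset members
    absent from the panel draw a warning, not an error.
    """
    snp_index = list(snp_index)
    if gene_subset is not None:
        unknown = [g for g in gene_subset if g not in finemap_results]
        if unknown:
            log.warning("max_cpp_annotation: %d gene(s) in subset not in panel "
                        "(e.g. %s)", len(unknown), unknown[0])
        genes = [g for g in gene_subset if g in finemap_results]
    else:
        genes = list(finemap_results)
    a = np.zeros(len(snp_index))
    for g in genes:
        res = finemap_results[g]
        pos = {s: i for i, s in enumerate(res.snps)}
        for j, snp in enumerate(snp_index):
            i = pos.get(snp)
            if i is not None and res.theta[i] == 1:
                a[j] = max(a[j], res.alpha[i])
    return a


def _merge_intervals(starts, ends):
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def rbp_annotation(sites, snp_chrom, snp_pos, flank: int = 100) -> pd.DataFrame:
    """Binary binding-site annotation per RNA-binding protein.

    ``sites`` maps RBP name -> BED-convention interval DataFrame (chrom,
    start, end; 0-based half-open). A SNP at 1-based position p is annotated
    1 for an RBP iff p lies within [start+1-flank, end+flank] of any of its
    (merged) sites.
    """
    snp_chrom = np.asarray(snp_chrom)
    snp_pos = np.asarray(snp_pos, int)
    out = {}
    for rbp, df in sites.items():
        col = np.zeros(snp_pos.size, dtype=int)
        for chrom, sub in df.groupby("chrom"):
            mask = snp_chrom == chrom
            if not mask.any() or len(sub) == 0:
                continue
            lo = sub["start"].to_numpy(int) + 1 - flank   # 1-based inclusive
            hi = sub["end"].to_numpy(int) + flank
            lo, hi = _merge_intervals(lo, hi)
            pos = snp_pos[mask]
            idx = np.searchsorted(lo, pos, side="right") - 1
            cov = (idx >= 0) & (pos <= hi[np.clip(idx, 0, len(hi) - 1)])
            col[mask] = cov.astype(int)
        out[rbp] = col
    return pd.DataFrame(out)


def rbp_annotation_matrix(sites, snps: pd.DataFrame,
                          flank: int = 100) -> AnnotationMatrix:
    """Wrap :func:`rbp_annotation` into an :class:`AnnotationMatrix`."""
    values = rbp_annotation(sites, snps["CHR"].to_numpy(), snps["BP"].to_numpy(),
                            flank=flank)
    return AnnotationMatrix(snps[["SNP", "CHR", "BP"]], values.astype(float))
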