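"""Stratified LD-score regression and partitioned heritability.

The model: for SNP j with sample size N, E[chi2_j] = N * sum_c tau_c * l(j,c)
+ N*b + 1, where l(j,c) = sum_k a_c(k) * r2_jk is the annotation-specific LD
score (squared correlations, including self-LD), tau_c the per-SNP
heritability contribution of annotation c, and N*b a confounding intercept
term. Estimation is weighted least squares of chi2 on {N*l(j,c)} with a free
intercept; inference is by contiguous-block delete-one jackknife.

Derived quantities: total h2 = sum_c tau_c * M_c (M_c = sum_k a_c(k), so
overlapping annotations do not double-count); per-annotation enrichment
(h2 share over SNP share, binary annotations only); and the standardized
effect size tau*_c = (M * sd_c / h2) * tau_c, the per-SNP heritability change
per standard-deviation increase of the annotation, comparable across traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AnnotationMatrix, LDMatrix, SumStats
from .errors import ArgumentError, IntegrityError, NumericError

__all__ = [
    "LDScoreMatrix", "TauEstimate", "ld_scores", "regress_partitioned",
    "standardize_tau", "block_jackknife", "JackknifeResult", "enrichment",
    "conditional_model", "mean_tau_star", "adjust_pvalues",
]


# ---------------------------------------------------------------------------
# LD scores


@dataclass
class LDScoreMatrix:
    """Per-SNP, per-annotation LD scores plus reference annotation metadata."""

    snps: list[str]
    scores: pd.DataFrame          # rows align with snps, one column per annotation
    m_annot: pd.Series            # M_c = sum_k a_c(k) over the reference panel
    sd_annot: pd.Series           # population sd of each annotation column
    m_ref: int                    # total reference SNP count M

    @property
    def names(self) -> list[str]:
        return list(self.scores.columns)

    def subset(self, names) -> "LDScoreMatrix":
        names = list(names)
        return LDScoreMatrix(self.snps, self.scores[names],
                             self.m_annot[names], self.sd_annot[names], self.m_ref)


def ld_scores(ld, annotations: AnnotationMatrix, n_ref: int | None = None,
              squared: bool = True) -> LDScoreMatrix:
    """Annotation-specific LD scores l(j,c) = sum_k a_c(k) * r2_jk.

    ``ld`` is an :class:`LDMatrix` (or raw square array) on the same SNP index
    as ``annotations``; the sum includes k = j (self-LD). When the
    correlations were estimated from a finite panel of ``n_ref`` individuals,
    the standard finite-sample bias adjustment r2 - (1 - r2)/(n_ref - 2) is
    applied. ``squared=False`` computes the literal unsquared-r sum; it
    exists only for unit testing and is not a supported analysis mode.
    """
    if isinstance(ld, LDMatrix):
        snps, r = ld.snps, ld.r
        if len(annotations) != len(snps):
            raise IntegrityError("annotation SNP index does not match LD matrix")
    else:
        r = np.asarray(ld, float)
        snps = list(annotations.snps["SNP"])
        if len(annotations) != r.shape[0]:
            raise IntegrityError("annotation SNP index does not match LD matrix")
    if squared:
        r2 = r**2
        if n_ref is not None:
            if n_ref <= 2:
                raise ArgumentError("n_ref must exceed 2 for bias adjustment")
            r2 = r2 - (1.0 - r2) / (n_ref - 2)
    else:
        r2 = r
    a = annotations.matrix()
    scores = pd.DataFrame(r2 @ a, columns=annotations.names)
    return LDScoreMatrix(snps=list(snps), scores=scores,
                         m_annot=annotations.m_annot(), sd_annot=annotations.sd(),
                         m_ref=len(annotations))


def ld_scores_from_panel(panel, annotations: AnnotationMatrix,
                         squared: bool = True) -> LDScoreMatrix:
    """LD scores with correlations estimated from a genotype panel."""
    ldm = panel.ld_matrix()
    return ld_scores(ldm, annotations, n_ref=panel.n_individuals, squared=squared)


# ---------------------------------------------------------------------------
# block jackknife


@dataclass
class JackknifeResult:
    estimate: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_one_sided: np.ndarray
    p_two_sided: np.ndarray
    deletes: np.ndarray           # n_blocks x dim delete-one estimates


def _block_slices(n_items: int, n_blocks: int):
    edges = np.linspace(0, n_items, n_blocks + 1).astype(int)
    return [(edges[b], edges[b + 1]) for b in range(n_blocks)]


def block_jackknife(statistic_fn, n_items: int, n_blocks: int = 200) -> JackknifeResult:
    """Contiguous-block delete-one jackknife of an arbitrary statistic.

    ``statistic_fn`` maps an integer index array (subset of range(n_items))
    to a scalar or vector estimate. SE^2 = (B-1)/B * sum_b (theta_(-b) -
    mean)^2; Z = theta_hat / SE; the one-sided p is the upper normal tail
    (enrichment-direction hypotheses), the two-sided p is also returned.
    """
    if n_blocks < 2:
        raise ArgumentError("block jackknife requires at least 2 blocks")
    if n_blocks > n_items:
        raise ArgumentError("more jackknife blocks than items")
    all_idx = np.arange(n_items)
    full = np.atleast_1d(np.asarray(statistic_fn(all_idx), float))
    deletes = np.empty((n_blocks, full.size))
    for b, (lo, hi) in enumerate(_block_slices(n_items, n_blocks)):
        idx = np.concatenate([all_idx[:lo], all_idx[hi:]])
        deletes[b] = np.atleast_1d(np.asarray(statistic_fn(idx), float))
    mean_del = deletes.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks
                 * np.sum((deletes - mean_del) ** 2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, full / se, np.where(full == 0, 0.0, np.inf * np.sign(full)))
    return JackknifeResult(estimate=full, se=se, z=z,
                           p_one_sided=stats.norm.sf(z),
                           p_two_sided=2 * stats.norm.sf(np.abs(z)),
                           deletes=deletes)


# ---------------------------------------------------------------------------
# partitioned regression


@dataclass
class TauEstimate:
    """Fitted partitioned-heritability model with jackknife inference."""

    names: list[str]
    tau: np.ndarray
    tau_se: np.ndarray
    tau_z: np.ndarray
    p_one_sided: np.ndarray
    p_two_sided: np.ndarray
    intercept: float
    intercept_se: float
    h2: float
    h2_se: float
    tau_star: np.ndarray
    tau_star_se: np.ndarray
    tau_star_z: np.ndarray
    tau_star_p_one_sided: np.ndarray
    m_annot: pd.Series
    sd_annot: pd.Series
    m_ref: int
    n_blocks: int
    tau_deletes: np.ndarray          # n_blocks x n_annotations
    tau_star_deletes: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "annotation": self.names, "tau": self.tau, "tau_se": self.tau_se,
            "tau_star": self.tau_star, "tau_star_se": self.tau_star_se,
            "Z": self.tau_z, "p_one_sided": self.p_one_sided,
        })


def standardize_tau(tau, m_ref, sd_annot, h2):
    """Standardized effect size tau* = (M * sd / h2) * tau."""
    if h2 <= 0:
        raise ArgumentError(f"h2 must be > 0 for tau* standardisation, got {h2}")
    sd_annot = np.asarray(sd_annot, float)
    if np.any(sd_annot <= 0):
        raise ArgumentError("annotation sd must be > 0 for tau* standardisation")
    return m_ref * sd_annot / h2 * np.asarray(tau, float)


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # the trailing right-singular vector spans the null space and
        # identifies the collinear columns
        _, _, vt = np.linalg.svd(design, full_matrices=False)
        bad = np.abs(vt[-1]) > 1e-6
        cols = [n for n, b in zip(names + ["intercept"], bad) if b]
        raise NumericError(f"rank-deficient design; collinear annotations: {cols}")


def regress_partitioned(sumstats: SumStats, ldscores: LDScoreMatrix,
                        weights_mode: str = "ldsc", n_blocks: int = 200,
                        base_annotation: str | None = None) -> TauEstimate:
    """Fit E[chi2_j] = N sum_c tau_c l(j,c) + intercept by weighted LS.

    ``weights_mode='ldsc'`` uses the standard heteroskedasticity/overcounting
    weights 1/(l_base * (1 + N*h2bar*l_base/M)^2) computed from a first-pass
    unweighted fit; ``'ols'`` fits unweighted (used by oracle tests).
    Inference comes from a contiguous-block delete-one jackknife; derived
    statistics (h2, tau*) are jackknifed through the same delete-block fits.
    """
    ss = sumstats.reindex(ldscores.snps)
    l = ldscores.scores.to_numpy(float)
    names = ldscores.names
    n_snps, n_ann = l.shape
    if n_snps < n_ann + 1:
        raise ArgumentError("need at least (n_annotations + 1) SNPs")
    nn = ss.n
    chi2 = ss.chi2
    design = np.column_stack([nn[:, None] * l, np.ones(n_snps)])
    _check_rank(design, names)

    if weights_mode == "ols":
        w = np.ones(n_snps)
    elif weights_mode == "ldsc":
        coef0, *_ = np.linalg.lstsq(design, chi2, rcond=None)
        h2_bar = max(float(coef0[:n_ann] @ ldscores.m_annot.to_numpy(float)), 1e-6)
        if base_annotation is None:
            base_annotation = "base" if "base" in names else names[0]
        l_base = np.maximum(ldscores.scores[base_annotation].to_numpy(float), 1.0)
        het = (1.0 + nn * h2_bar * l_base / ldscores.m_ref) ** 2
        w = 1.0 / (l_base * het)
    else:
        raise ArgumentError(f"unknown weights_mode {weights_mode!r}")
    sw = np.sqrt(w)

    m_annot = ldscores.m_annot.to_numpy(float)
    sd_annot = ldscores.sd_annot.to_numpy(float)

    def fit(idx):
        coef, *_ = np.linalg.lstsq(design[idx] * sw[idx, None], chi2[idx] * sw[idx],
                                   rcond=None)
        return coef

    def derived(coef):
        tau = coef[:n_ann]
        h2 = float(tau @ m_annot)
        tau_star = (ldscores.m_ref * sd_annot / h2 * tau if h2 > 0
                    else np.full(n_ann, np.nan))
        return np.concatenate([tau, [coef[-1]], [h2], tau_star])

    jk = block_jackknife(lambda idx: derived(fit(idx)), n_snps, n_blocks=n_blocks)
    est, se = jk.estimate, jk.se
    tau, tau_se = est[:n_ann], se[:n_ann]
    tau_star = est[n_ann + 2:]
    tau_star_se = se[n_ann + 2:]
    return TauEstimate(
        names=names, tau=tau, tau_se=tau_se,
        tau_z=jk.z[:n_ann], p_one_sided=jk.p_one_sided[:n_ann],
        p_two_sided=jk.p_two_sided[:n_ann],
        intercept=float(est[n_ann]), intercept_se=float(se[n_ann]),
        h2=float(est[n_ann + 1]), h2_se=float(se[n_ann + 1]),
        tau_star=tau_star, tau_star_se=tau_star_se,
        tau_star_z=jk.z[n_ann + 2:],
        tau_star_p_one_sided=jk.p_one_sided[n_ann + 2:],
        m_annot=ldscores.m_annot, sd_annot=ldscores.sd_annot,
        m_ref=ldscores.m_ref, n_blocks=n_blocks,
        tau_deletes=jk.deletes[:, :n_ann],
        tau_star_deletes=jk.deletes[:, n_ann + 2:],
    )


# ---------------------------------------------------------------------------
# enrichment and conditional analysis


def enrichment(tau_estimate: TauEstimate,
               annotations: AnnotationMatrix) -> pd.DataFrame:
    """Per-annotation heritability enrichment (h2 share / SNP share).

    Defined for binary annotations only; for continuous annotations the
    standardized tau* is the supported effect-size measure. The jackknife
    p tests enrichment > 1, reusing the delete-block tau fits.
    """
    if annotations.names != tau_estimate.names:
        raise IntegrityError("annotation columns do not match the fitted model")
    a = annotations.matrix()
    for name in annotations.names:
        if not annotations.is_binary(name):
            raise ArgumentError(
                f"enrichment is unsupported for continuous annotation "
                f"{name!r}; report tau* instead")
    m_c = a.sum(axis=0)
    m_tot = float(len(annotations))

    def enr_from_tau(tau):
        sigma2 = a @ tau                     # fitted per-SNP heritability
        h2 = sigma2.sum()
        h2_c = a.T @ sigma2 / 1.0            # sum of sigma2 over members
        return (h2_c / h2) / (m_c / m_tot)

    full = enr_from_tau(tau_estimate.tau)
    deletes = np.stack([enr_from_tau(t) for t in tau_estimate.tau_deletes])
    mean_del = deletes.mean(axis=0)
    b = deletes.shape[0]
    se = np.sqrt((b - 1) / b * np.sum((deletes - mean_del) ** 2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (full - 1.0) / se, 0.0)
    return pd.DataFrame({
        "annotation": annotations.names, "enrichment": full, "enrichment_se": se,
        "p_one_sided": stats.norm.sf(z),
        "M_c": m_c, "prop_snps": m_c / m_tot,
    })


def conditional_model(sumstats: SumStats, ldscores: LDScoreMatrix,
                      focus_annotation: str, baseline_annotations,
                      **regress_kwargs) -> pd.Series:
    """tau* and jackknife p for a focus annotation conditional on a baseline.

    One joint regression with baseline + focus columns; when iterating over
    several focus annotations, call this once per focus (each focus is fitted
    conditional on the baseline only, never on the other foci).
    """
    baseline = list(baseline_annotations)
    if focus_annotation in baseline:
        raise ArgumentError(f"focus annotation {focus_annotation!r} already in "
                            f"baseline")
    sub = ldscores.subset(baseline + [focus_annotation])
    est = regress_partitioned(sumstats, sub, **regress_kwargs)
    i = est.names.index(focus_annotation)
    # significance is judged on tau (the tau* rescaling is a positive factor
    # whose jackknife can degenerate when a delete-block h2 crosses zero)
    return pd.Series({
        "annotation": focus_annotation,
        "tau": est.tau[i], "tau_se": est.tau_se[i],
        "tau_star": est.tau_star[i], "tau_star_se": est.tau_star_se[i],
        "Z": est.tau_z[i], "p_one_sided": est.p_one_sided[i],
    })


def mean_tau_star(estimates) -> tuple[float, float]:
    """Plain mean of tau* across a set of fitted focus annotations.

    ``estimates`` is a sequence of :class:`TauEstimate`-derived (tau*,
    delete-block tau*) pairs for a common block structure; the jackknife SE
    of the mean reuses the delete-block values. For a single annotation this
    reduces to that annotation's tau* and SE.
    """
    stars = np.array([e[0] for e in estimates], float)
    deletes = np.stack([np.asarray(e[1], float) for e in estimates])  # k x B
    mean_deletes = deletes.mean(axis=0)                               # B
    b = mean_deletes.size
    mean_del = mean_deletes.mean()
    se = np.sqrt((b - 1) / b * np.sum((mean_deletes - mean_del) ** 2))
    return float(stars.mean()), float(se)


def adjust_pvalues(p, method: str = "bh", alpha: float = 0.05,
                   n_tests: int | None = None) -> np.ndarray:
    """Multiple-testing flags: Benjamini-Hochberg or Bonferroni.

    ``n_tests`` lets the Bonferroni denominator exceed len(p) when the
    analysis tested more hypotheses than are being flagged here.
    """
    p = np.asarray(p, float)
    if method == "bh":
        return multipletests(p, alpha=alpha, method="fdr_bh")[0]
    if method == "bonferroni":
        n = n_tests if n_tests is not None else p.size
        return p < alpha / n
    raise ArgumentError(f"unknown adjustment method {method!r}")
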