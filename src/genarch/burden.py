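"""Rare-variant genic burden association.

Pipeline: classify variants (disruptive / damaging / missense / other),
build per-individual per-transcript burden counts under nested
MAF-by-class masks, test burden against case status with Firth-penalised
logistic regression (finite estimates under complete separation), and
combine cohorts by inverse-variance-weighted meta-analysis.

Class definitions: "disruptive" covers frame-shift, splice-site, exon loss,
stop gained, start loss and transcription ablation consequences; "damaging"
are missense variants called deleterious by every supplied prediction
algorithm; remaining missense variants are "missense". Burden is the number
of qualifying variant sites at which an individual carries at least one
alternate allele (homozygotes count once; allele-dosage counting is
available behind a flag). Transcripts with fewer than five individuals of
non-zero burden are flagged excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import chi2, norm

from .errors import ArgumentError, ConvergenceError, NumericError

log = logging.getLogger(__name__)

DISRUPTIVE_CONSEQUENCES = frozenset({
    "frameshift", "frameshift_variant", "frame_shift",
    "splice_site", "splice_site_variant", "splice_variant",
    "splice_acceptor", "splice_acceptor_variant",
    "splice_donor", "splice_donor_variant",
    "exon_loss", "exon_loss_variant",
    "stop_gained", "start_lost", "start_loss",
    "transcription_ablation",
})

MISSENSE_CONSEQUENCES = frozenset({"missense", "missense_variant"})

_KNOWN_OTHER = frozenset({
    "synonymous_variant", "synonymous", "intron_variant", "intergenic_variant",
    "5_prime_utr_variant", "3_prime_utr_variant", "upstream_gene_variant",
    "downstream_gene_variant", "non_coding_transcript_variant",
})

VARIANT_CLASSES = ("disruptive", "damaging", "missense", "other")


def classify_variants(variants: pd.DataFrame,
                      algorithm_flags: list[str] | None = None) -> pd.DataFrame:
    """Assign a variant class from the consequence term and algorithm flags.

    Order of precedence: disruptive consequence; else missense with ALL
    supplied algorithm flags deleterious -> damaging; else missense ->
    missense; else other. Unknown consequence terms are classified "other"
    with a logged warning, never dropped.
    """
    if algorithm_flags is None:
        from .simulate import PREDICTION_ALGORITHMS
        algorithm_flags = [a for a in PREDICTION_ALGORITHMS
                           if a in variants.columns]
    cons = variants["consequence"].str.lower().str.replace("-", "_", regex=False)
    out = variants.copy()
    disruptive = cons.isin(DISRUPTIVE_CONSEQUENCES)
    missense = cons.isin(MISSENSE_CONSEQUENCES)
    unknown = ~disruptive & ~missense & ~cons.isin(_KNOWN_OTHER)
    if unknown.any():
        terms = sorted(cons[unknown].unique())
        log.warning("classify_variants: unknown consequence term(s) %s "
                    "classified as 'other'", terms)
    if algorithm_flags:
        all_deleterious = variants[algorithm_flags].astype(bool).all(axis=1)
    else:
        all_deleterious = pd.Series(False, index=variants.index)
    cls = np.where(disruptive, "disruptive",
                   np.where(missense & all_deleterious, "damaging",
                            np.where(missense, "missense", "other")))
    out["variant_class"] = cls
    return out


@dataclass(frozen=True)
class BurdenMask:
    """A MAF-threshold x variant-class mask.

    Class sets are the nested families disruptive c disruptive+damaging c
    disruptive+damaging+missense; MAF thresholds 0.01 and 0.005 are the
    standard choices (others may be passed explicitly).
    """

    maf_threshold: float = 0.01
    classes: frozenset = frozenset({"disruptive", "damaging"})

    def label(self) -> str:
        return f"maf{self.maf_threshold:g}_" + "+".join(sorted(self.classes))

    @staticmethod
    def standard_masks() -> list["BurdenMask"]:
        families = [frozenset({"disruptive"}),
                    frozenset({"disruptive", "damaging"}),
                    frozenset({"disruptive", "damaging", "missense"})]
        return [BurdenMask(maf, fam) for maf in (0.01, 0.005) for fam in families]


@dataclass
class BurdenTable:
    """Per-individual, per-transcript burden counts with inclusion flags."""

    burden: pd.DataFrame          # individuals x transcripts
    included: pd.Series           # transcript -> bool (>= 5 non-zero carriers)
    mask: BurdenMask


def build_burden(genotypes: np.ndarray, variants: pd.DataFrame,
                 mask: BurdenMask, count_mode: str = "sites",
                 min_carriers: int = 5) -> BurdenTable:
    """Collapse qualifying variants into per-transcript burden counts.

    ``variants`` needs columns transcript, variant_class and an allele
    frequency (gnomad_af used when present/non-missing, else cohort_af).
    ``count_mode='sites'`` counts variant sites with >= 1 alternate allele;
    ``'dosage'`` sums alternate-allele counts.
    """
    if count_mode not in ("sites", "dosage"):
        raise ArgumentError(f"unknown count_mode {count_mode!r}")
    if "variant_class" not in variants.columns:
        raise ArgumentError("variants must be classified first "
                            "(run classify_variants)")
    af = variants["gnomad_af"] if "gnomad_af" in variants.columns else None
    if af is None:
        af = variants["cohort_af"]
    elif "cohort_af" in variants.columns:
        af = af.fillna(variants["cohort_af"])
    qualifies = (variants["variant_class"].isin(mask.classes)
                 & (af < mask.maf_threshold)).to_numpy()
    geno = np.asarray(genotypes)
    carrier = (geno > 0).astype(int) if count_mode == "sites" else geno.astype(int)
    transcripts = pd.unique(variants["transcript"])
    cols = {}
    for t in transcripts:
        sel = (variants["transcript"] == t).to_numpy() & qualifies
        cols[t] = carrier[:, sel].sum(axis=1) if sel.any() else np.zeros(
            geno.shape[0], dtype=int)
    burden = pd.DataFrame(cols)
    included = (burden > 0).sum(axis=0) >= min_carriers
    return BurdenTable(burden=burden, included=included, mask=mask)


# ---------------------------------------------------------------------------
# Firth-penalised logistic regression


def _penalized_loglik(x, y, beta):
    eta = x @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    p = expit(eta)
    w = p * (1.0 - p)
    info = x.T @ (x * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_solve(x, y, fixed: dict[int, float] | None = None,
                 max_iter: int = 100, tol: float = 1e-8):
    """Maximise the Jeffreys-penalised log-likelihood by Newton iteration.

    ``fixed`` pins coordinates (used for profile likelihood and LR tests);
    the hat-matrix score correction and the penalty always use the full
    design. Returns (beta, penalized loglik, information, n_iter).
    """
    n, p = x.shape
    fixed = fixed or {}
    free = np.array([j for j in range(p) if j not in fixed], dtype=int)
    beta = np.zeros(p)
    for j, v in fixed.items():
        beta[j] = v
    ll = _penalized_loglik(x, y, beta)
    info = None
    for it in range(1, max_iter + 1):
        eta = x @ beta
        prob = expit(eta)
        w = np.clip(prob * (1.0 - prob), 1e-12, None)
        info = x.T @ (x * w[:, None])
        try:
            cho = cho_factor(info)
        except LinAlgError as exc:
            raise NumericError("singular information matrix in Firth fit; "
                               "check for constant columns") from exc
        # leverages h_i of the weighted hat matrix
        s = cho_solve(cho, x.T)                       # p x n
        h = w * np.einsum("ij,ji->i", x, s)
        score = x.T @ (y - prob + h * (0.5 - prob))
        if free.size == 0:
            break
        info_ff = info[np.ix_(free, free)]
        try:
            delta_free = np.linalg.solve(info_ff, score[free])
        except np.linalg.LinAlgError as exc:
            raise NumericError("singular free-coordinate information in "
                               "Firth fit") from exc
        # step-halving on the penalised log-likelihood
        step = 1.0
        for _ in range(40):
            trial = beta.copy()
            trial[free] += step * delta_free
            ll_new = _penalized_loglik(x, y, trial)
            if ll_new >= ll - 1e-10:
                break
            step /= 2.0
        else:
            raise ConvergenceError("Firth step-halving failed",
                                   {"iteration": it, "loglik": ll})
        beta = trial
        improved = ll_new - ll
        ll = ll_new
        if np.max(np.abs(step * delta_free)) < tol or improved < 1e-12:
            return beta, ll, info, it
    if free.size == 0:
        return beta, ll, info, 0
    raise ConvergenceError(
        f"Firth fit did not converge in {max_iter} iterations",
        {"loglik": ll, "beta": beta.tolist()})


@dataclass
class BurdenResult:
    """Firth burden test for one transcript/mask (or a meta-analysis)."""

    transcript: str
    mask: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float                      # penalised likelihood-ratio p
    p_wald: float
    n_carriers_case: int
    n_carriers_control: int
    included: bool = True
    converged: bool = True
    n_iter: int = 0
    ci_method: str = "profile"
    diagnostics: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {"transcript": self.transcript, "mask": self.mask,
                "beta": self.beta, "se": self.se, "or": self.or_,
                "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
                "p_wald": self.p_wald,
                "n_carriers_case": self.n_carriers_case,
                "n_carriers_control": self.n_carriers_control,
                "included": self.included}


def _profile_ci(x, y, k, beta_hat, ll_max, se, level=0.95, max_iter=100):
    """Profile penalised-likelihood CI for coordinate k by bisection."""
    target = ll_max - chi2.ppf(level, 1) / 2.0

    def deficit(v):
        _, ll, _, _ = _firth_solve(x, y, fixed={k: v}, max_iter=max_iter)
        return ll - target

    bounds = []
    step0 = max(se, 0.5)
    for direction in (-1.0, 1.0):
        lo_v, hi_v = beta_hat[k], beta_hat[k]
        f_hi = deficit(hi_v)
        found = False
        for i in range(1, 60):
            lo_v = hi_v
            hi_v = beta_hat[k] + direction * i * step0
            f_lo, f_hi = f_hi, deficit(hi_v)
            if f_hi < 0:
                found = True
                break
        if not found:
            bounds.append(direction * np.inf)
            continue
        from scipy.optimize import brentq
        root = brentq(deficit, min(lo_v, hi_v), max(lo_v, hi_v), xtol=1e-6)
        bounds.append(root)
    return min(bounds), max(bounds)


def firth_logistic(burden, case_status, covariates=None,
                   ci_method: str = "profile", level: float = 0.95,
                   max_iter: int = 100, transcript: str = "transcript",
                   mask_label: str = "mask") -> BurdenResult:
    """Firth-penalised logistic regression of case status on burden.

    The design is [intercept, burden, covariates]; estimates remain finite
    under complete separation (the defining property of the Jeffreys
    penalty). The reported p-value is the penalised likelihood-ratio test of
    the burden coefficient; a Wald p is also computed. Confidence intervals
    default to profile penalised likelihood; ``ci_method='wald'`` selects
    Wald intervals.
    """
    b = np.asarray(burden, float)
    y = np.asarray(case_status, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ArgumentError("case_status must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ArgumentError("need at least one case and one control")
    cols = [np.ones_like(b), b]
    names = ["intercept", "burden"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != b.size:
            cov = cov.T
        for j in range(cov.shape[1]):
            if np.ptp(cov[:, j]) > 0:
                cols.append(cov[:, j])
                names.append(f"cov{j}")
    if np.ptp(b) == 0:
        raise NumericError("burden is constant; nothing to test")
    x = np.column_stack(cols)

    beta, ll_max, info, n_iter = _firth_solve(x, y, max_iter=max_iter)
    cov_beta = np.linalg.inv(info)
    se = float(np.sqrt(cov_beta[1, 1]))
    bk = float(beta[1])

    # penalised likelihood-ratio test of the burden coefficient
    _, ll0, _, _ = _firth_solve(x, y, fixed={1: 0.0}, max_iter=max_iter)
    lr = max(2.0 * (ll_max - ll0), 0.0)
    p_lrt = float(chi2.sf(lr, 1))
    zw = bk / se
    p_wald = float(2.0 * norm.sf(abs(zw)))

    if ci_method == "profile":
        lo, hi = _profile_ci(x, y, 1, beta, ll_max, se, level=level,
                             max_iter=max_iter)
    elif ci_method == "wald":
        q = norm.ppf(0.5 + level / 2.0)
        lo, hi = bk - q * se, bk + q * se
    else:
        raise ArgumentError(f"unknown ci_method {ci_method!r}")

    carriers = b > 0
    return BurdenResult(
        transcript=transcript, mask=mask_label, beta=bk, se=se,
        or_=float(np.exp(bk)), ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)), p=p_lrt, p_wald=p_wald,
        n_carriers_case=int(carriers[y == 1].sum()),
        n_carriers_control=int(carriers[y == 0].sum()),
        converged=True, n_iter=n_iter, ci_method=ci_method,
        diagnostics={"loglik": ll_max, "lr": lr})


def burden_scan(table: BurdenTable, case_status, covariates=None,
                **firth_kwargs) -> pd.DataFrame:
    """Firth-test every included transcript of a burden table."""
    rows = []
    for t in table.burden.columns:
        if not table.included[t]:
            rows.append(BurdenResult(
                transcript=t, mask=table.mask.label(), beta=np.nan, se=np.nan,
                or_=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                p_wald=np.nan, n_carriers_case=0, n_carriers_control=0,
                included=False).to_row())
            continue
        res = firth_logistic(table.burden[t].to_numpy(), case_status,
                             covariates=covariates, transcript=t,
                             mask_label=table.mask.label(), **firth_kwargs)
        rows.append(res.to_row())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# meta-analysis and QQ diagnostics


def ivw_meta(betas, ses, transcript: str = "meta",
             mask_label: str = "meta") -> BurdenResult:
    """Inverse-variance-weighted fixed-effect meta-analysis of log-ORs.

    beta_meta = sum(beta_j/se_j^2) / sum(1/se_j^2); SE = (sum 1/se_j^2)^-1/2;
    the CI is Wald at 95% and the p two-sided normal. A single cohort passes
    through with a warning.
    """
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if betas.size == 0:
        raise ArgumentError("no cohorts to meta-analyse")
    if np.any(~np.isfinite(ses)) or np.any(ses <= 0):
        raise ArgumentError("all standard errors must be finite and > 0")
    if betas.size == 1:
        warnings.warn("single cohort: meta-analysis is a passthrough",
                      stacklevel=2)
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    return BurdenResult(
        transcript=transcript, mask=mask_label, beta=beta, se=se,
        or_=float(np.exp(beta)), ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)), p=float(2 * norm.sf(abs(z))),
        p_wald=float(2 * norm.sf(abs(z))), n_carriers_case=0,
        n_carriers_control=0, ci_method="wald")


def genomewide_qq(p_values) -> tuple[pd.DataFrame, float]:
    """Expected-vs-observed -log10 p quantiles and the inflation factor.

    lambda = median observed chi2 / median expected chi2 (0.4549 for 1 df).
    """
    p = np.sort(np.asarray(p_values, float))
    if p.size < 10:
        raise ArgumentError("need at least 10 p-values for a QQ summary")
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    chi_obs = chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    lam = float(np.median(chi_obs) / chi2.ppf(0.5, 1))
    table = pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(np.clip(p, 1e-300, 1.0)),
    })
    return table, lam
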