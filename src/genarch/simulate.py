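"""Synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the downstream estimators
assume, without any real cohort:

* LD-blocked genotype panels from a latent Gaussian threshold model: two
  independent haplotype draws per individual, each a latent normal vector
  with block-constant correlation rho, thresholded at the allele-frequency
  quantile. This yields Hardy-Weinberg-consistent genotypes in {0,1,2} with
  controllable (discretisation-attenuated) LD.
* GWAS summary statistics under the infinitesimal-within-annotation model:
  per-SNP causal effects beta_j ~ N(0, sigma2_j) with sigma2_j =
  sum_c a_c(j) * tau_c, so E[chi2_j] = 1 + N sum_c tau_c l(j,c) holds by
  construction. A shared environmental score implements the confounding
  intercept term.
* cis-eQTL reference panels with a sparse causal architecture and exact
  realized cis-heritability per gene.
* rare-variant case/control cohorts with gene-level burden effects at a
  specified odds ratio, simulated consequence labels and per-algorithm
  deleteriousness flags, and sex + principal-component covariates.

Every generator is a pure function of its arguments including the seed, and
ships a ``SimulationTruth``-style record of the generating parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .containers import AnnotationMatrix, LDMatrix, SumStats
from .errors import ArgumentError, ModelError

log = logging.getLogger(__name__)

PREDICTION_ALGORITHMS = ("sift", "polyphen2", "lrt", "mutationtaster2",
                         "mutationassessor", "provean")


# ---------------------------------------------------------------------------
# genotype panels


@dataclass
class GenotypePanel:
    """Individuals x SNPs genotype matrix with SNP metadata and LD blocks."""

    genotypes: np.ndarray              # n x m, int8 values 0/1/2
    snps: pd.DataFrame                 # SNP, CHR, BP, A1, A2, maf, block

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["SNP"])

    def maf_empirical(self) -> np.ndarray:
        freq = self.genotypes.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def standardized(self) -> np.ndarray:
        g = self.genotypes.astype(float)
        mu = g.mean(axis=0)
        sd = g.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ModelError("monomorphic SNP in panel; increase n or MAF")
        return (g - mu) / sd

    def ld_matrix(self) -> LDMatrix:
        r = np.corrcoef(self.standardized(), rowvar=False)
        return LDMatrix(self.snp_ids, r)


def simulate_ld_panel(n_individuals: int, n_snps: int, block_size: int = 10,
                      rho=0.0, maf_range=(0.05, 0.5),
                      seed: int = 0) -> GenotypePanel:
    """Simulate an LD-blocked genotype panel.

    Within each block of ``block_size`` SNPs the latent haplotype Gaussians
    share correlation rho; blocks are independent. ``rho`` is either a
    scalar or a (low, high) range from which each block draws its own
    correlation — heterogeneous LD across blocks is what makes LD scores
    vary between SNPs, as in real genomes. The realized genotype correlation
    is attenuated relative to rho by the double thresholding and should be
    measured, not assumed.
    """
    if n_individuals < 2:
        raise ArgumentError("need at least 2 individuals")
    lo, hi = maf_range
    if not 0 < lo <= hi <= 0.5:
        raise ArgumentError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, "
                            f"got {maf_range}")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)
    thresh = norm.ppf(maf)
    blocks = np.arange(n_snps) // block_size
    n_blocks = int(blocks.max()) + 1
    if np.ndim(rho) == 0:
        rho_block = np.full(n_blocks, float(rho))
    else:
        rlo, rhi = rho
        rho_block = rng.uniform(rlo, rhi, size=n_blocks)
    if np.any(rho_block < 0) or np.any(rho_block >= 1):
        raise ArgumentError(f"rho must lie in [0, 1), got {rho}")
    geno = np.zeros((n_individuals, n_snps), dtype=np.int8)
    for _hap in range(2):
        shared = rng.standard_normal((n_individuals, n_blocks))
        noise = rng.standard_normal((n_individuals, n_snps))
        latent = (np.sqrt(rho_block)[blocks] * shared[:, blocks]
                  + np.sqrt(1.0 - rho_block)[blocks] * noise)
        geno += (latent < thresh).astype(np.int8)
    snps = pd.DataFrame({
        "SNP": [f"s{j:05d}" for j in range(n_snps)],
        "CHR": "1",
        "BP": 1000 * (np.arange(n_snps) + 1),
        "A1": "A", "A2": "G",
        "maf": maf, "block": blocks,
    })
    return GenotypePanel(genotypes=geno, snps=snps)


# ---------------------------------------------------------------------------
# GWAS summary statistics


@dataclass
class GwasTruth:
    """Generating parameters of a simulated GWAS."""

    tau: dict
    h2: float
    intercept_inflation: float
    n_gwas: int
    seed: int
    beta: np.ndarray = field(repr=False, default=None)

    def to_yaml(self, path) -> None:
        data = {"tau": {k: float(v) for k, v in self.tau.items()},
                "h2": float(self.h2),
                "intercept_inflation": float(self.intercept_inflation),
                "n_gwas": int(self.n_gwas), "seed": int(self.seed),
                "beta": [float(b) for b in self.beta]}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def simulate_gwas(panel: GenotypePanel, annotations: AnnotationMatrix, tau,
                  intercept_inflation: float = 0.0, n_gwas: int | None = None,
                  seed: int = 0) -> tuple[SumStats, GwasTruth]:
    """Simulate GWAS marginal statistics with annotation-stratified h2.

    ``tau`` maps annotation name -> per-SNP variance coefficient (or is an
    array aligned to the annotation columns). Effects are drawn per SNP as
    beta_j ~ N(0, sum_c a_c(j) tau_c) on standardized genotypes, the
    phenotype is scaled to unit variance and the marginal z-score per SNP is
    sqrt(N) * cor(x_j, y). ``intercept_inflation`` is the expected additive
    chi2 inflation (the N*b term), implemented as a shared environmental
    score proportional to the mean standardized genotype.
    """
    if isinstance(tau, dict):
        tau_vec = np.array([tau.get(name, 0.0) for name in annotations.names])
    else:
        tau_vec = np.asarray(tau, float)
        if tau_vec.shape != (len(annotations.names),):
            raise ArgumentError("tau length does not match annotation count")
    a = annotations.matrix()
    sigma2 = a @ tau_vec
    if np.any(sigma2 < -1e-12):
        j = int(np.argmin(sigma2))
        raise ModelError(f"negative per-SNP variance at SNP "
                         f"{annotations.snps['SNP'].iloc[j]!r}")
    sigma2 = np.maximum(sigma2, 0.0)
    h2 = float(sigma2.sum())
    if intercept_inflation < 0:
        raise ArgumentError("intercept_inflation must be >= 0")

    n_panel = panel.n_individuals
    n_gwas = n_panel if n_gwas is None else n_gwas
    if n_gwas > n_panel:
        raise ArgumentError(f"n_gwas ({n_gwas}) exceeds panel size ({n_panel})")

    rng = np.random.default_rng(seed)
    xs = panel.standardized()[:n_gwas]
    m = panel.n_snps
    beta = rng.standard_normal(m) * np.sqrt(sigma2)
    genetic = xs @ beta

    confound = np.zeros(n_gwas)
    conf_var = 0.0
    if intercept_inflation > 0:
        # shared score s = X R^-1 1 has identical correlation with every SNP,
        # so it inflates each chi2 by the same amount regardless of LD —
        # a stylised stratification axis producing the Nb intercept term
        r_emp = np.corrcoef(xs, rowvar=False)
        w_conf = np.linalg.solve(r_emp + 1e-6 * np.eye(m), np.ones(m))
        q = float(w_conf.sum())          # = 1'R^-1 1 = var of raw score
        conf_var = intercept_inflation * q / n_gwas
        score = xs @ w_conf
        confound = np.sqrt(conf_var) * score / score.std(ddof=0)
    env_var = 1.0 - h2 - conf_var
    if env_var <= 0:
        raise ModelError(f"h2 ({h2:.3f}) plus confounding variance "
                         f"({conf_var:.3f}) reaches 1; no room for noise")
    y = genetic + confound + rng.standard_normal(n_gwas) * np.sqrt(env_var)

    yc = (y - y.mean()) / y.std(ddof=0)
    z = np.sqrt(n_gwas) * (xs.T @ yc) / n_gwas
    table = panel.snps[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    table["Z"] = z
    table["N"] = float(n_gwas)
    truth = GwasTruth(tau=dict(zip(annotations.names, tau_vec)), h2=h2,
                      intercept_inflation=intercept_inflation, n_gwas=n_gwas,
                      seed=seed, beta=beta)
    return SumStats(table), truth


def baseline_annotation(panel: GenotypePanel, extra: dict | None = None
                        ) -> AnnotationMatrix:
    """All-ones base annotation (plus optional named extra columns)."""
    values = {"base": np.ones(panel.n_snps)}
    if extra:
        values.update({k: np.asarray(v, float) for k, v in extra.items()})
    return AnnotationMatrix(panel.snps[["SNP", "CHR", "BP"]],
                            pd.DataFrame(values))


# ---------------------------------------------------------------------------
# eQTL reference panels


@dataclass
class GeneExpression:
    """Expression of one gene plus its causal-architecture truth."""

    gene: str
    snp_indices: np.ndarray           # global indices of the cis window
    expression: np.ndarray            # per-individual, unit variance
    causal_indices: np.ndarray        # global indices of causal SNPs
    beta: np.ndarray                  # effects on standardized genotypes
    cis_h2: float


@dataclass
class EqtlStudy:
    """A panel plus per-gene expression vectors with recorded truth."""

    panel: GenotypePanel
    genes: list[GeneExpression]

    def marginal_z(self, gene: GeneExpression) -> np.ndarray:
        """Marginal eQTL z-scores for the gene's cis window."""
        xs = self.panel.standardized()[:, gene.snp_indices]
        n = self.panel.n_individuals
        y = gene.expression
        yc = (y - y.mean()) / y.std(ddof=0)
        return np.sqrt(n) * (xs.T @ yc) / n


def simulate_eqtl_panel(panel: GenotypePanel, n_genes: int,
                        causal_per_gene: int = 1, cis_h2: float = 0.1,
                        seed: int = 0) -> EqtlStudy:
    """Simulate per-gene expression with a sparse cis-causal architecture.

    The panel's SNPs are split into ``n_genes`` contiguous cis windows.
    Causal SNPs are drawn uniformly within each window; the genetic component
    is rescaled so its realized sample variance equals ``cis_h2`` exactly
    (a variance-targeting convention that makes heritability-recovery tests
    sharp), noise brings the total variance to one.
    """
    if not 0 <= cis_h2 < 1:
        raise ArgumentError(f"cis_h2 must be in [0, 1), got {cis_h2}")
    window = panel.n_snps // n_genes
    if window < 1:
        raise ArgumentError("fewer SNPs than genes")
    if causal_per_gene > window:
        raise ArgumentError(f"causal_per_gene ({causal_per_gene}) exceeds the "
                            f"cis window size ({window})")
    rng = np.random.default_rng(seed)
    xs = panel.standardized()
    n = panel.n_individuals
    genes = []
    for g in range(n_genes):
        idx = np.arange(g * window, (g + 1) * window)
        causal_local = rng.choice(window, size=causal_per_gene, replace=False)
        causal = idx[np.sort(causal_local)]
        beta = rng.standard_normal(causal_per_gene)
        noise = rng.standard_normal(n)
        if cis_h2 > 0:
            graw = xs[:, causal] @ beta
            scale = np.sqrt(cis_h2) / graw.std(ddof=0)
            beta = beta * scale
            genetic = graw * scale
            expr = genetic + noise * np.sqrt(1.0 - cis_h2)
        else:
            beta = np.zeros(causal_per_gene)
            expr = noise
        genes.append(GeneExpression(
            gene=f"gene{g:04d}", snp_indices=idx, expression=expr,
            causal_indices=causal, beta=beta, cis_h2=cis_h2))
    return EqtlStudy(panel=panel, genes=genes)


# ---------------------------------------------------------------------------
# rare-variant cohorts


@dataclass
class RareCohort:
    """Synthetic rare-variant case/control cohort.

    ``variants`` carries per-variant metadata (transcript, consequence,
    per-algorithm deleteriousness flags, gnomAD-style external AF);
    ``genotypes`` is individuals x variants (0/1/2); ``phenotypes`` holds
    status, sex and principal components indexed by sample ID.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    phenotypes: pd.DataFrame
    truth: "RareTruth"

    @property
    def samples(self) -> list[str]:
        return list(self.phenotypes.index)

    def covariate_matrix(self) -> np.ndarray:
        cols = [c for c in self.phenotypes.columns if c != "status"]
        return self.phenotypes[cols].to_numpy(float)


@dataclass
class RareTruth:
    """Generating parameters of a rare-variant cohort."""

    per_gene_or: dict
    qualifying: dict               # gene -> list of qualifying variant ids
    n_cases_target: int
    n_controls_target: int
    seed: int

    def to_yaml(self, path) -> None:
        data = {"per_gene_or": {k: float(v) for k, v in self.per_gene_or.items()},
                "qualifying": {k: list(v) for k, v in self.qualifying.items()},
                "n_cases_target": self.n_cases_target,
                "n_controls_target": self.n_controls_target, "seed": self.seed}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


_CONSEQUENCES = ("missense_variant", "frameshift_variant", "stop_gained",
                 "splice_acceptor_variant", "synonymous_variant")
_CONSEQUENCE_P = (0.55, 0.10, 0.05, 0.05, 0.25)


def simulate_rare_cohort(n_cases: int, n_controls: int, n_genes: int,
                         per_gene_or, variant_maf_spec=(1e-4, 5e-3),
                         variants_per_gene: int = 8,
                         deleterious_flag_prob: float = 0.75,
                         sex_effect: float = 0.2, n_pcs: int = 20,
                         seed: int = 0) -> RareCohort:
    """Simulate a rare-variant cohort with gene-level burden effects.

    Rare alleles are drawn per variant as Binomial(2, MAF) with MAF
    log-uniform in ``variant_maf_spec``. Case status follows a logistic model
    with log(per_gene_or) per unit of qualifying burden (disruptive or
    unanimous-damaging variants) plus sex and null principal components; the
    intercept is solved so the expected case fraction matches the requested
    arm sizes. Consequence labels and per-algorithm deleteriousness calls are
    simulated as exchangeable Bernoulli flags.
    """
    per_gene_or = np.broadcast_to(np.asarray(per_gene_or, float), (n_genes,))
    if np.any(per_gene_or <= 0):
        raise ArgumentError("per_gene_or must be > 0 for every gene")
    lo, hi = variant_maf_spec
    if not 0 < lo <= hi < 0.01:
        raise ArgumentError("variant MAFs must lie in (0, 0.01)")
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    n_var = n_genes * variants_per_gene

    maf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_var))
    geno = rng.binomial(2, maf, size=(n, n_var)).astype(np.int8)
    cons = rng.choice(_CONSEQUENCES, size=n_var, p=_CONSEQUENCE_P)
    # every gene carries at least one disruptive site so its qualifying
    # burden is never structurally empty
    from .burden import DISRUPTIVE_CONSEQUENCES
    for g in range(n_genes):
        sl = slice(g * variants_per_gene, (g + 1) * variants_per_gene)
        if not np.any(np.isin(cons[sl], list(DISRUPTIVE_CONSEQUENCES))):
            cons[g * variants_per_gene] = "frameshift_variant"
    flags = {alg: rng.random(n_var) < deleterious_flag_prob
             for alg in PREDICTION_ALGORITHMS}
    gene_of = np.repeat(np.arange(n_genes), variants_per_gene)

    variants = pd.DataFrame({
        "id": [f"v{j:05d}" for j in range(n_var)],
        "chrom": "22",
        "pos": 45_500_000 + 50 * np.arange(n_var),
        "ref": "G", "alt": "A",
        "transcript": [f"ENST{g:08d}" for g in gene_of],
        "consequence": cons,
        "gnomad_af": maf,
        "cohort_af": geno.mean(axis=0) / 2.0,
    })
    for alg, f in flags.items():
        variants[alg] = f

    # qualifying burden: disruptive consequence, or missense with unanimous
    # deleterious calls (mirrors the damaging-mask definition downstream)
    flag_mat = np.column_stack(list(flags.values()))
    disruptive = np.isin(cons, list(DISRUPTIVE_CONSEQUENCES))
    damaging = (cons == "missense_variant") & flag_mat.all(axis=1)
    qualifying = disruptive | damaging

    burden = np.zeros((n, n_genes))
    qual_ids: dict[str, list[str]] = {}
    for g in range(n_genes):
        cols = np.where((gene_of == g) & qualifying)[0]
        qual_ids[f"ENST{g:08d}"] = [f"v{j:05d}" for j in cols]
        if cols.size:
            burden[:, g] = (geno[:, cols] > 0).sum(axis=1)
        exp_carriers = min(n_cases, n_controls) * (
            1.0 - np.prod(1.0 - 2 * maf[cols] * (1 - maf[cols])) if cols.size else 0.0)
        if exp_carriers < 1:
            warnings.warn(f"gene ENST{g:08d}: expected qualifying carriers per "
                          f"arm < 1; burden test will have ~0 power",
                          stacklevel=2)

    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, n_pcs))
    lin = burden @ np.log(per_gene_or) + sex_effect * (sex - 0.5)
    target = n_cases / n

    def mean_prev(alpha):
        return expit(alpha + lin).mean() - target

    alpha = brentq(mean_prev, -30.0, 30.0)
    status = (rng.random(n) < expit(alpha + lin)).astype(int)

    pheno = pd.DataFrame({"status": status, "sex": sex},
                         index=pd.Index([f"ind{i:05d}" for i in range(n)],
                                        name="sample"))
    for k in range(n_pcs):
        pheno[f"PC{k + 1}"] = pcs[:, k]

    truth = RareTruth(
        per_gene_or={f"ENST{g:08d}": per_gene_or[g] for g in range(n_genes)},
        qualifying=qual_ids, n_cases_target=n_cases,
        n_controls_target=n_controls, seed=seed)
    return RareCohort(variants=variants, genotypes=geno, phenotypes=pheno,
                      truth=truth)
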