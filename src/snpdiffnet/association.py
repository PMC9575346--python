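"""Single-SNP association and split-sample edge validation.

Per-SNP analysis is a covariate-adjusted maximum-likelihood logistic
regression under the additive (per-allele) genetic model, reporting the
odds ratio with Wald 95% confidence interval and p-value. Edge
validation re-tests one gene pair on an independent cohort: densities
fitted by class on a random half, an unpenalized logistic regression of
the other half's labels on the single log-density-ratio feature, and
the Wald p-value of that coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .ingest import GenotypeMatrix, SnpGeneMap
from .jdinac import PairDensityModel, PairKDE, log_density_ratio

__all__ = [
    "AssociationResult",
    "EdgeValidationResult",
    "snp_logistic",
    "association_table",
    "validate_edge",
]

Z_95 = float(norm.ppf(0.975))  # 1.959964...


@dataclass
class AssociationResult:
    snp_id: str
    gene: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    covariates_used: list[str]

    def __post_init__(self) -> None:
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("confidence interval must bracket the odds ratio")
        if not 0 <= self.p <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class EdgeValidationResult:
    gene_i: str
    gene_j: str
    p: float
    split_seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p-value outside [0, 1]")


def snp_logistic(
    genotypes: Sequence[float],
    Y: Sequence[int],
    Z: np.ndarray | pd.DataFrame | None = None,
    *,
    snp_id: str = "snp",
    gene: str = "",
    covariate_names: Sequence[str] | None = None,
) -> AssociationResult:
    """Additive-model logistic association of one SNP with case status.

    OR = exp(beta) per allele-count unit; 95% CI = exp(beta +- 1.96*SE);
    p is the two-sided Wald p-value of the SNP coefficient.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(Y, dtype=int)
    keep = ~np.isnan(g)
    g, y = g[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError(f"{snp_id}: both classes must be present")
    if np.ptp(g) == 0:
        raise ValueError(f"{snp_id}: constant genotype, no association estimable")
    if Z is None:
        Zm = np.empty((len(g), 0))
        names: list[str] = []
    else:
        if covariate_names is None:
            names = list(Z.columns) if isinstance(Z, pd.DataFrame) else [
                f"z{i}" for i in range(np.asarray(Z).shape[1])
            ]
        else:
            names = list(covariate_names)
        Zm = np.asarray(Z, dtype=float)[keep]
    X = np.column_stack([np.ones(len(g)), g, Zm])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as err:  # separation / singularity surface here
        raise ValueError(f"{snp_id}: logistic regression failed ({err})") from err
    if not res.mle_retvals.get("converged", True):
        raise ValueError(f"{snp_id}: logistic regression did not converge")
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or se > 50:
        raise ValueError(f"{snp_id}: unstable fit (quasi-separation)")
    return AssociationResult(
        snp_id=snp_id,
        gene=gene,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        p=float(res.pvalues[1]),
        covariates_used=names,
    )


def association_table(
    g: GenotypeMatrix,
    snp_map: SnpGeneMap | None = None,
    covariates: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-SNP adjusted ORs for all SNPs (optionally restricted to genes).

    Raw p-values by default; ``bh_correct`` adds a Benjamini–Hochberg
    adjusted column.
    """
    Z = g.covariate_matrix(covariates) if (covariates or len(g.covariates.columns)) else None
    names = list(covariates) if covariates is not None else list(g.covariates.columns)
    rows = []
    for k, snp in enumerate(g.snp_ids):
        gene = snp_map.snp_to_gene.get(snp, "") if snp_map else ""
        if genes is not None and gene not in genes:
            continue
        res = snp_logistic(
            g.values[:, k], g.y, Z, snp_id=snp, gene=gene, covariate_names=names
        )
        rows.append(
            {
                "snp_id": res.snp_id,
                "gene": res.gene,
                "OR": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
            }
        )
    df = pd.DataFrame(rows, columns=["snp_id", "gene", "OR", "ci_low", "ci_high", "p"])
    if bh_correct and len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_adjust"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def validate_edge(
    si: Sequence[float],
    sj: Sequence[float],
    Y: Sequence[int],
    seed: int = 0,
    *,
    gene_i: str = "gene_i",
    gene_j: str = "gene_j",
) -> EdgeValidationResult:
    """Split-sample density-ratio test of one gene pair.

    The cohort is split in half (stratified by class); case and control
    bivariate densities are fitted on the first half, the log ratio is
    evaluated for the second half, and the Wald p-value of that single
    feature in an unpenalized logistic regression is returned.
    """
    x = np.asarray(si, dtype=float)
    z = np.asarray(sj, dtype=float)
    y = np.asarray(Y, dtype=int)
    if not (len(x) == len(z) == len(y)):
        raise ValueError("score vectors and labels must have equal length")
    rng = np.random.default_rng(seed)
    half1, half2 = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 20:
            raise ValueError("need >= 10 samples per class in each half")
        perm = rng.permutation(len(idx))
        n1 = len(idx) // 2
        half1.append(idx[perm[:n1]])
        half2.append(idx[perm[n1:]])
    d1 = np.sort(np.concatenate(half1))
    d2 = np.sort(np.concatenate(half2))
    model = PairDensityModel(
        gene_i=gene_i,
        gene_j=gene_j,
        kde_case=PairKDE(np.column_stack([x, z])[d1[y[d1] == 1]]),
        kde_control=PairKDE(np.column_stack([x, z])[d1[y[d1] == 0]]),
    )
    feat = log_density_ratio(model, np.column_stack([x, z])[d2])
    X = np.column_stack([np.ones(len(d2)), feat])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y[d2], X).fit(disp=0, maxiter=200)
    if np.ptp(feat) == 0:
        raise ValueError(f"degenerate density fit for edge ({gene_i}, {gene_j})")
    return EdgeValidationResult(
        gene_i=gene_i, gene_j=gene_j, p=float(res.pvalues[1]), split_seed=seed
    )
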