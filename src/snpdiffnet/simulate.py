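"""Case–control genotype cohorts with planted differential gene–gene dependence.

The generator draws, per group, a latent multivariate normal vector with
one dimension per SNP and discretizes each coordinate at the
Hardy–Weinberg thresholds implied by the SNP's minor allele frequency,
so marginally P(2) = maf^2, P(1) = 2*maf*(1-maf), P(0) = (1-maf)^2.
Dependence is a Gaussian copula: SNPs of one gene share an exchangeable
latent correlation (mimicking local LD), and a planted edge
(gene_a, gene_b, rho_case, rho_control) induces a cross-gene latent
correlation calibrated so that the correlation of the two *latent
gene-mean scores* equals rho in the respective group. Cases and
controls therefore differ in joint law only on planted edges with
rho_case != rho_control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ingest import GenotypeMatrix, SnpGeneMap

__all__ = [
    "CovariateSpec",
    "PlantedEdge",
    "SimConfig",
    "TruthNetwork",
    "simulate_cohort",
    "study_like_config",
    "nearest_feasible_star",
    "STUDY_GENES",
]

# Obesity/DNA-repair gene panel of the kind used in SNP-based
# breast-cancer candidate studies; purely nominal for simulation.
STUDY_GENES = [
    "LEP", "LEPR", "RETN", "XRCC6", "XRCC5", "ADIPOQ", "ADIPOR1", "ADIPOR2",
    "UCP2", "PPARD", "IFI30", "GPR30", "STAT3", "VISFATIN", "CDH13", "PTPN1",
    "PON1", "FTO", "MC4R", "PPARG",
]


@dataclass(frozen=True)
class PlantedEdge:
    """A gene pair whose latent gene-score correlation differs by group."""

    gene_a: str
    gene_b: str
    rho_case: float
    rho_control: float

    @property
    def differential(self) -> bool:
        return self.rho_case != self.rho_control

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: ``normal`` with (mean, sd) per group or ``bernoulli``
    with a prevalence per group."""

    name: str
    family: str  # "normal" | "bernoulli"
    control_params: tuple[float, ...]
    case_params: tuple[float, ...]

    def draw(self, n: int, case: bool, rng: np.random.Generator) -> np.ndarray:
        params = self.case_params if case else self.control_params
        if self.family == "normal":
            mu, sd = params
            return rng.normal(mu, sd, size=n)
        if self.family == "bernoulli":
            (p,) = params
            return rng.binomial(1, p, size=n).astype(float)
        raise ValueError(f"unknown covariate family {self.family!r}")


def _default_covariates() -> list[CovariateSpec]:
    # BMI-like continuous confounder and menopause-like binary confounder,
    # group-shifted as in the source cohort's demographics.
    return [
        CovariateSpec("bmi", "normal", (24.01, 3.11), (24.36, 3.46)),
        CovariateSpec("menopause", "bernoulli", (0.281,), (0.335,)),
    ]


@dataclass
class SimConfig:
    """Full description of a synthetic cohort.

    ``maf`` may be a scalar (shared by all SNPs) or one value per SNP in
    (0, 0.5]. ``snps_per_gene`` may be a scalar or one count per gene.
    ``within_gene_rho`` is the exchangeable latent correlation between
    SNPs of the same gene (local-LD surrogate).
    """

    n_case: int = 953
    n_control: int = 963
    genes: list[str] = field(default_factory=lambda: list(STUDY_GENES))
    snps_per_gene: int | Sequence[int] = 5
    maf: float | Sequence[float] = 0.3
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    covariate_specs: list[CovariateSpec] = field(default_factory=_default_covariates)
    within_gene_rho: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_edges = [
            e if isinstance(e, PlantedEdge) else PlantedEdge(*e) for e in self.planted_edges
        ]
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene list contains duplicates")
        counts = self.snp_counts()
        if any(k < 1 for k in counts):
            raise ValueError("snps_per_gene must be positive")
        mafs = self.maf_vector()
        if np.any(mafs <= 0) or np.any(mafs > 0.5):
            raise ValueError("all MAFs must lie in (0, 0.5]")
        if not 0 <= self.within_gene_rho < 1:
            raise ValueError("within_gene_rho must lie in [0, 1)")
        seen: set[tuple[str, str]] = set()
        for e in self.planted_edges:
            if e.gene_a == e.gene_b:
                raise ValueError(f"planted edge references a single gene: {e.gene_a!r}")
            for g in (e.gene_a, e.gene_b):
                if g not in self.genes:
                    raise ValueError(f"planted edge references unknown gene {g!r}")
            if not (abs(e.rho_case) < 1 and abs(e.rho_control) < 1):
                raise ValueError(f"edge {e.pair}: |rho| must be < 1")
            if e.pair in seen:
                raise ValueError(f"duplicate planted edge {e.pair}")
            seen.add(e.pair)

    def snp_counts(self) -> list[int]:
        if isinstance(self.snps_per_gene, int):
            return [self.snps_per_gene] * len(self.genes)
        counts = list(self.snps_per_gene)
        if len(counts) != len(self.genes):
            raise ValueError("snps_per_gene must match the gene list length")
        return counts

    def snp_ids(self) -> list[str]:
        return [
            f"{g}_snp{k + 1}" for g, c in zip(self.genes, self.snp_counts()) for k in range(c)
        ]

    def maf_vector(self) -> np.ndarray:
        n_snps = sum(self.snp_counts())
        if np.isscalar(self.maf):
            return np.full(n_snps, float(self.maf))
        mafs = np.asarray(self.maf, dtype=float)
        if mafs.shape != (n_snps,):
            raise ValueError(f"need one MAF per SNP ({n_snps}), got {mafs.shape}")
        return mafs

    def snp_gene_map(self) -> SnpGeneMap:
        pairs = [
            (f"{g}_snp{k + 1}", g)
            for g, c in zip(self.genes, self.snp_counts())
            for k in range(c)
        ]
        return SnpGeneMap.from_pairs(pairs)


@dataclass
class TruthNetwork:
    """The planted edge set of a simulated cohort."""

    edges: list[PlantedEdge]

    @property
    def differential_edges(self) -> list[PlantedEdge]:
        return [e for e in self.edges if e.differential]

    @property
    def differential_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.differential_edges}

    def write(self, path: str | Path, sep: str = "\t") -> None:
        pd.DataFrame(
            [
                {
                    "gene_a": e.gene_a,
                    "gene_b": e.gene_b,
                    "rho_case": e.rho_case,
                    "rho_control": e.rho_control,
                }
                for e in self.edges
            ],
            columns=["gene_a", "gene_b", "rho_case", "rho_control"],
        ).to_csv(path, sep=sep, index=False)


def _latent_correlation(config: SimConfig, case: bool) -> np.ndarray:
    """SNP-level latent correlation for one group.

    Within-gene blocks are exchangeable at ``within_gene_rho``. For a
    planted edge with gene-score correlation rho, every cross-gene SNP
    pair gets c = rho * sqrt((1+(k_a-1)w)(1+(k_b-1)w) / (k_a k_b)), the
    unique exchangeable value making the two latent gene means correlate
    exactly rho.
    """
    counts = config.snp_counts()
    offsets = np.concatenate([[0], np.cumsum(counts)])
    gene_index = {g: i for i, g in enumerate(config.genes)}
    n = offsets[-1]
    w = config.within_gene_rho
    corr = np.eye(n)
    for i in range(len(counts)):
        block = slice(offsets[i], offsets[i + 1])
        corr[block, block] = w
    corr[np.diag_indices(n)] = 1.0
    for e in config.planted_edges:
        rho = e.rho_case if case else e.rho_control
        ia, ib = gene_index[e.gene_a], gene_index[e.gene_b]
        ka, kb = counts[ia], counts[ib]
        c = rho * np.sqrt((1 + (ka - 1) * w) * (1 + (kb - 1) * w) / (ka * kb))
        a = slice(offsets[ia], offsets[ia + 1])
        b = slice(offsets[ib], offsets[ib + 1])
        corr[a, b] = c
        corr[b, a] = c
    return corr


def _cholesky_or_raise(corr: np.ndarray, config: SimConfig, group: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        edges = ", ".join(str(e.pair) for e in config.planted_edges)
        raise ValueError(
            f"the {group}-group latent correlation implied by planted edges "
            f"[{edges}] is not positive definite; reduce |rho| or the edge set"
        ) from None


def _draw_group(
    config: SimConfig,
    n: int,
    case: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    corr = _latent_correlation(config, case)
    chol = _cholesky_or_raise(corr, config, "case" if case else "control")
    z = rng.standard_normal((n, corr.shape[0])) @ chol.T
    mafs = config.maf_vector()
    # HWE thresholds on the standard-normal scale:
    # genotype 0 iff z <= Phi^-1((1-maf)^2), 2 iff z > Phi^-1(1-maf^2).
    t0 = norm.ppf((1 - mafs) ** 2)
    t1 = norm.ppf(1 - mafs**2)
    return (z > t0).astype(float) + (z > t1)


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, TruthNetwork]:
    """Draw a reproducible case–control cohort.

    Returns the genotype matrix (controls first, then cases; labels and
    covariates attached) and the planted truth network. All randomness
    derives from ``config.seed`` through named child streams, so
    identical configs give bit-identical cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    s_control, s_case, s_covar = root.spawn(3)
    geno_control = _draw_group(config, config.n_control, False, np.random.default_rng(s_control))
    geno_case = _draw_group(config, config.n_case, True, np.random.default_rng(s_case))
    values = np.vstack([geno_control, geno_case])
    y = np.concatenate([np.zeros(config.n_control, int), np.ones(config.n_case, int)])
    sample_ids = [f"ctl{str(i + 1).zfill(5)}" for i in range(config.n_control)] + [
        f"case{str(i + 1).zfill(5)}" for i in range(config.n_case)
    ]
    cov_rng = np.random.default_rng(s_covar)
    covs = {}
    for spec in config.covariate_specs:
        covs[spec.name] = np.concatenate(
            [
                spec.draw(config.n_control, False, cov_rng),
                spec.draw(config.n_case, True, cov_rng),
            ]
        )
    genotypes = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=config.snp_ids(),
        values=values,
        y=y,
        covariates=pd.DataFrame(covs),
    )
    return genotypes, TruthNetwork(edges=list(config.planted_edges))


def nearest_feasible_star(
    hub: str,
    leaves: Sequence[str],
    rho: float,
    rho_control: float = 0.0,
    eig_floor: float = 0.01,
) -> list[PlantedEdge]:
    """Planted edges for a hub star, repaired to a valid correlation.

    A star in which one gene correlates rho with m independent partners
    is a valid correlation structure only for |rho| < 1/sqrt(m); e.g.
    rho = 0.6 with four partners is impossible for ANY joint
    distribution. This helper projects the requested star onto the
    nearest correlation matrix (Higham projection with an eigenvalue
    floor) and returns planted edges for every implied pair: the
    hub–leaf coupling is pulled slightly below the request and a small
    induced leaf–leaf correlation appears.
    """
    from statsmodels.stats.correlation_tools import corr_nearest

    m = len(leaves)
    if m < 1:
        raise ValueError("need at least one leaf")
    target = np.eye(m + 1)
    target[0, 1:] = target[1:, 0] = rho
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        repaired = corr_nearest(target, threshold=eig_floor)
    hub_leaf = float(repaired[0, 1])
    leaf_leaf = float(repaired[1, 2]) if m > 1 else 0.0
    edges = [PlantedEdge(hub, leaf, hub_leaf, rho_control) for leaf in leaves]
    if abs(leaf_leaf) > 1e-6:
        for i in range(m):
            for j in range(i + 1, m):
                edges.append(PlantedEdge(leaves[i], leaves[j], leaf_leaf, rho_control))
    return edges


def study_like_config(
    seed: int = 0,
    *,
    n_case: int = 953,
    n_control: int = 963,
) -> SimConfig:
    """A cohort emulating the motivating case–control study's scale.

    ~1,900 subjects, 20 candidate genes covered by ~100 SNPs with a
    spread of realistic allele frequencies, a differential hub (LEPR
    coupled to LEP, RETN, CDH13 and GPR30 in cases only) plus one
    off-hub differential edge, and BMI/menopause-like confounders.
    """
    genes = list(STUDY_GENES)
    n_snps = 5 * len(genes)
    mafs = np.round(np.linspace(0.08, 0.45, n_snps), 3)
    edges = [
        PlantedEdge("LEPR", "LEP", 0.45, 0.0),
        PlantedEdge("LEPR", "RETN", 0.45, 0.0),
        PlantedEdge("LEPR", "CDH13", 0.45, 0.0),
        PlantedEdge("LEPR", "GPR30", 0.45, 0.0),
        PlantedEdge("PPARD", "UCP2", 0.5, 0.0),
        PlantedEdge("XRCC5", "XRCC6", 0.3, 0.3),  # shared (non-differential) dependence
    ]
    return SimConfig(
        n_case=n_case,
        n_control=n_control,
        genes=genes,
        snps_per_gene=5,
        maf=mafs,
        planted_edges=edges,
        seed=seed,
    )
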