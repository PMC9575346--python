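"""Differential gene-interaction network inference from gene risk scores.

The model: with binary phenotype Y and gene scores S_1..S_p, fit

    logit P(Y=1) = a0 + sum_t a_t Z_t
                 + sum_{i<j} b_ij * ln[ f1_ij(S_i,S_j) / f0_ij(S_i,S_j) ]

subject to an L1 constraint on the b_ij, where f1_ij and f0_ij are the
case- and control-conditional bivariate densities of (S_i, S_j),
estimated by product-Gaussian kernel density estimation. Densities are
fitted on one half of a random sample split and the penalized logistic
model on the other half (then the halves swap roles); repeating over T
random splits yields, per pair, an importance score

    omega_ij = number of splits t with b_ij,t != 0   (0 <= omega <= T).

Pairs with high omega form the differential network; nodes of degree >=
min_degree are reported as hub genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logsumexp
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .ingest import GeneScoreMatrix

__all__ = [
    "PairKDE",
    "PairDensityModel",
    "JdinacConfig",
    "ImportanceTable",
    "DifferentialNetwork",
    "fit_pair_density",
    "log_density_ratio",
    "jdinac_single_split",
    "jdinac_importance",
    "build_network",
    "find_hubs",
]

_COEF_TOL = 1e-8  # below this a penalized coefficient counts as zero


class PairKDE:
    """Bivariate product-Gaussian kernel density estimate.

    Bandwidths follow the per-dimension Silverman rule for two
    dimensions, h_d = sigma_d * n^(-1/6). A zero-variance dimension
    falls back to 1% of the data range (or 1e-3 for a constant column),
    with a warning.
    """

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of paired scores")
        if not np.isfinite(data).all():
            raise ValueError("non-finite values in density-fit data")
        if data.shape[0] < 5:
            raise ValueError(f"need >= 5 paired observations, got {data.shape[0]}")
        self.data = data
        self.n = data.shape[0]
        sd = data.std(axis=0, ddof=1)
        h = sd * self.n ** (-1 / 6)
        for d in range(2):
            if h[d] <= 0:
                rng_d = float(data[:, d].max() - data[:, d].min())
                h[d] = 0.01 * rng_d if rng_d > 0 else 1e-3
                warnings.warn(
                    f"dimension {d} has zero variance; bandwidth fallback {h[d]:g}",
                    stacklevel=2,
                )
        self.bandwidths = h

    def logpdf(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        h1, h2 = self.bandwidths
        u1 = (points[:, None, 0] - self.data[None, :, 0]) / h1
        u2 = (points[:, None, 1] - self.data[None, :, 1]) / h2
        log_k = -0.5 * (u1 * u1 + u2 * u2)
        return logsumexp(log_k, axis=1) - math.log(self.n * 2 * math.pi * h1 * h2)

    def pdf(self, points: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(points))


def fit_pair_density(x: np.ndarray, y: np.ndarray) -> PairKDE:
    """Fit the bivariate KDE of two genes' scores (one group)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("score vectors must have equal length")
    return PairKDE(np.column_stack([x, y]))


@dataclass
class PairDensityModel:
    """Group-conditional joint densities of one gene pair."""

    gene_i: str
    gene_j: str
    kde_case: PairKDE
    kde_control: PairKDE

    @property
    def n_case(self) -> int:
        return self.kde_case.n

    @property
    def n_control(self) -> int:
        return self.kde_control.n

    @property
    def bandwidths(self) -> dict[str, np.ndarray]:
        return {"case": self.kde_case.bandwidths, "control": self.kde_control.bandwidths}


def log_density_ratio(
    model: PairDensityModel,
    points: np.ndarray,
    floor: float = 1e-10,
) -> np.ndarray:
    """ln(f1/f0) at the given (S_i, S_j) points, floored for finiteness.

    Both densities are clipped below at ``floor`` before the log, so a
    point far outside both supports contributes ln(floor/floor) = 0
    rather than an infinity.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    log_floor = math.log(floor)
    l1 = np.maximum(model.kde_case.logpdf(points), log_floor)
    l0 = np.maximum(model.kde_control.logpdf(points), log_floor)
    return l1 - l0


@dataclass
class JdinacConfig:
    """Tuning knobs of the multi-split inference procedure."""

    T: int = 20
    split_fraction: float = 0.5
    cv_folds: int = 5
    lambda_grid: Sequence[float] | str = "auto"
    n_lambdas: int = 20
    lambda_min_ratio: float = 0.01
    cv_rule: str = "1se"  # "1se" (sparser, better null calibration) or "min"
    density_floor: float = 1e-10
    penalize_covariates: bool = False
    min_score: int | None = None  # None -> ceil(T/4)
    min_hub_degree: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be positive")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.density_floor <= 0:
            raise ValueError("density_floor must be positive")
        if self.cv_rule not in ("1se", "min"):
            raise ValueError("cv_rule must be '1se' or 'min'")

    @property
    def effective_min_score(self) -> int:
        return math.ceil(self.T / 4) if self.min_score is None else self.min_score


def _pairs(gene_ids: Sequence[str]) -> list[tuple[int, int]]:
    p = len(gene_ids)
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


def _stratified_half_split(
    y: np.ndarray,
    order: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced random split; membership keyed to sample identity.

    ``order`` is a canonical (id-sorted) ordering of sample indices, so
    the same physical samples land in the same half regardless of the
    input row order.
    """
    d1, d2 = [], []
    for cls in (0, 1):
        idx = order[y[order] == cls]
        n1 = int(round(fraction * len(idx)))
        perm = rng.permutation(len(idx))
        d1.append(idx[perm[:n1]])
        d2.append(idx[perm[n1:]])
    return np.sort(np.concatenate(d1)), np.sort(np.concatenate(d2))


def _pair_features(
    scores: np.ndarray,
    y: np.ndarray,
    fit_idx: np.ndarray,
    eval_idx: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    floor: float,
) -> np.ndarray:
    """Log-density-ratio features for eval_idx, densities fitted on fit_idx."""
    feats = np.empty((len(eval_idx), len(pairs)))
    case_idx = fit_idx[y[fit_idx] == 1]
    ctl_idx = fit_idx[y[fit_idx] == 0]
    for k, (i, j) in enumerate(pairs):
        model = PairDensityModel(
            gene_i=str(i),
            gene_j=str(j),
            kde_case=PairKDE(scores[np.ix_(case_idx, [i, j])]),
            kde_control=PairKDE(scores[np.ix_(ctl_idx, [i, j])]),
        )
        feats[:, k] = log_density_ratio(model, scores[np.ix_(eval_idx, [i, j])], floor)
    return feats


_COVARIATE_SCALE = 1e4  # rescaling that makes covariate penalty negligible


def _fit_l1_logit(
    feats: np.ndarray, y: np.ndarray, Z: np.ndarray, lam: float, penalize_covariates: bool
) -> np.ndarray:
    """L1 logistic fit returning (pair coefficients, covariate coefficients).

    ``lam`` is on the glmnet per-observation scale. Covariates are left
    effectively unpenalized by inflating their columns by a large factor
    (an exact penalty-factor rescaling for the L1 norm), matching their
    role as adjustments rather than selection candidates.
    """
    scale = 1.0 if penalize_covariates else _COVARIATE_SCALE
    X = np.hstack([feats, Z * scale]) if Z.size else feats
    clf = LogisticRegression(
        l1_ratio=1,
        C=1.0 / (lam * len(y)),
        solver="liblinear",
        intercept_scaling=100.0,
        tol=1e-4,
        max_iter=1000,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    coef = clf.coef_[0]
    n_pair = feats.shape[1]
    params = np.concatenate([[clf.intercept_[0]], coef[:n_pair], coef[n_pair:] * scale])
    return params


def _heldout_deviance(
    params: np.ndarray, feats: np.ndarray, y: np.ndarray, Z: np.ndarray
) -> float:
    X = np.hstack([np.ones((len(y), 1)), feats, Z]) if Z.size else np.hstack(
        [np.ones((len(y), 1)), feats]
    )
    eta = np.clip(X @ params, -30, 30)
    ll = y * eta - np.log1p(np.exp(eta))
    return float(-2.0 * ll.mean())


def _lambda_grid(
    feats: np.ndarray, y: np.ndarray, Z: np.ndarray, cfg: JdinacConfig
) -> np.ndarray:
    if not isinstance(cfg.lambda_grid, str):
        grid = np.sort(np.asarray(list(cfg.lambda_grid), dtype=float))[::-1]
        if (grid <= 0).any():
            raise ValueError("lambda grid must be positive")
        return grid
    # glmnet-style: lambda_max is the smallest penalty that zeroes every
    # pair coefficient, computed from the unpenalized baseline fit.
    X0 = np.hstack([np.ones((len(y), 1)), Z]) if Z.size else np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = sm.Logit(y, X0).fit(disp=0, maxiter=200)
    resid = y - base.predict(X0)
    lam_max = max(np.abs(feats.T @ resid).max() / feats.shape[0], 1e-6)
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambdas)


def _cv_lasso_select(
    feats: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None,
    cfg: JdinacConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cross-validated L1 logistic on pair features.

    The penalty is chosen by ``cv_folds``-fold cross-validated deviance:
    either the minimizer ("min") or the sparser one-standard-error
    choice ("1se", default). Returns the pair coefficients of the refit
    on all samples at the chosen penalty.
    """
    n = feats.shape[0]
    Z = np.empty((n, 0)) if Z is None or Z.size == 0 else np.asarray(Z, dtype=float)
    n_pair = feats.shape[1]
    grid = _lambda_grid(feats, y, Z, cfg)

    def run_cv(seed: int) -> np.ndarray:
        skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed)
        dev = np.zeros((cfg.cv_folds, len(grid)))
        for f, (train, test) in enumerate(skf.split(feats, y)):
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                raise RuntimeError("cross-validation fold with a single class")
            for g, lam in enumerate(grid):
                params = _fit_l1_logit(
                    feats[train], y[train], Z[train], lam, cfg.penalize_covariates
                )
                dev[f, g] = _heldout_deviance(params, feats[test], y[test], Z[test])
        return dev

    cv_seed = int(rng.integers(0, 2**31 - 1))
    try:
        dev = run_cv(cv_seed)
    except RuntimeError:
        dev = run_cv(int(rng.integers(0, 2**31 - 1)))  # re-draw folds once
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    if cfg.cv_rule == "1se":
        se = dev[:, best].std(ddof=1) / math.sqrt(cfg.cv_folds)
        # grid is descending, so the first index within one SE is the
        # largest (sparsest) acceptable penalty
        best = int(np.flatnonzero(mean_dev <= mean_dev[best] + se)[0])
    params = _fit_l1_logit(feats, y, Z, grid[best], cfg.penalize_covariates)
    return params[1 : 1 + n_pair]


def jdinac_single_split(
    S: GeneScoreMatrix,
    Y: Sequence[int],
    Z: np.ndarray | pd.DataFrame | None,
    cfg: JdinacConfig,
    split_seed: int,
) -> set[tuple[str, str]]:
    """One random split of the JDINAC procedure.

    Samples are split in half (stratified by class). Densities are
    estimated on one half and the penalized model fitted on the other;
    the roles then swap, and a pair counts as selected for this split if
    its coefficient is non-zero in either direction.
    """
    y = np.asarray(Y, dtype=int)
    scores = np.asarray(S.scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("gene scores contain missing values; impute before inference")
    if min(np.sum(y == 0), np.sum(y == 1)) < 10:
        raise ValueError("need >= 10 samples in each class")
    if S.n_genes < 2:
        raise ValueError("need at least 2 genes")
    Zm = None if Z is None else np.asarray(Z, dtype=float)
    pairs = _pairs(S.gene_ids)
    order = np.array(sorted(range(len(S.sample_ids)), key=lambda k: S.sample_ids[k]))
    rng = np.random.default_rng(split_seed)
    d1, d2 = _stratified_half_split(y, order, cfg.split_fraction, rng)

    selected = np.zeros(len(pairs), dtype=bool)
    for fit_idx, eval_idx in ((d1, d2), (d2, d1)):
        feats = _pair_features(scores, y, fit_idx, eval_idx, pairs, cfg.density_floor)
        coefs = _cv_lasso_select(
            feats,
            y[eval_idx],
            None if Zm is None else Zm[eval_idx],
            cfg,
            rng,
        )
        selected |= np.abs(coefs) > _COEF_TOL
    genes = S.gene_ids
    return {tuple(sorted((genes[i], genes[j]))) for k, (i, j) in enumerate(pairs) if selected[k]}


@dataclass
class ImportanceTable:
    """Per-pair selection counts omega over T random splits."""

    omega: dict[tuple[str, str], int]
    T: int
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pair, w in self.omega.items():
            if not 0 <= w <= self.T:
                raise ValueError(f"omega for {pair} outside [0, {self.T}]")

    def ranked(self) -> list[tuple[tuple[str, str], int]]:
        """Pairs by omega descending, ties lexicographic."""
        return sorted(self.omega.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene1": a, "gene2": b, "importance": w, "T": self.T}
            for (a, b), w in self.ranked()
        ]
        return pd.DataFrame(rows, columns=["gene1", "gene2", "importance", "T"])

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def _split_seeds(cfg: JdinacConfig) -> np.ndarray:
    return np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=cfg.T)


def jdinac_importance(
    S: GeneScoreMatrix,
    Y: Sequence[int],
    Z: np.ndarray | pd.DataFrame | None = None,
    cfg: JdinacConfig | None = None,
    progress: bool = False,
) -> ImportanceTable:
    """Importance scores omega_ij over T random splits.

    Split seeds are spawned deterministically from ``cfg.seed``, so the
    result is reproducible for a fixed configuration.
    """
    cfg = cfg or JdinacConfig()
    omega: dict[tuple[str, str], int] = {
        tuple(sorted((S.gene_ids[i], S.gene_ids[j]))): 0 for i, j in _pairs(S.gene_ids)
    }
    iterator: Iterator[int] = iter(_split_seeds(cfg))
    if progress:
        from tqdm import tqdm

        iterator = iter(tqdm(list(iterator), desc="JDINAC splits"))
    for split_seed in iterator:
        for pair in jdinac_single_split(S, Y, Z, cfg, int(split_seed)):
            omega[pair] += 1
    return ImportanceTable(omega=omega, T=cfg.T, gene_ids=list(S.gene_ids))


@dataclass
class DifferentialNetwork:
    """Thresholded differential network with hub annotations."""

    nodes: list[str]
    edges: list[tuple[str, str, int]]  # (gene1, gene2, omega), rank order
    min_score: int
    T: int
    min_hub_degree: int = 4

    @property
    def hubs(self) -> list[str]:
        return find_hubs(self, self.min_hub_degree)

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {n: 0 for n in self.nodes}
        for a, b, _ in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        hubs = set(self.hubs)
        for n in self.nodes:
            g.add_node(n, hub=n in hubs)
        for rank, (a, b, w) in enumerate(self.edges, start=1):
            g.add_edge(a, b, omega=w, rank=rank)
        return g

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, _ in self.edges:
                fh.write(f"{a}\tinteracts\t{b}\n")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), path)


def build_network(imp: ImportanceTable, min_score: int) -> DifferentialNetwork:
    """Retain pairs with omega >= min_score as the differential network.

    Edges are ranked by omega descending with lexicographic tie-breaks;
    nodes are the endpoints of retained edges.
    """
    if not 0 <= min_score <= imp.T:
        raise ValueError(f"min_score must lie in [0, {imp.T}]")
    edges = [(a, b, w) for (a, b), w in imp.ranked() if w >= min_score]
    nodes = sorted({g for a, b, _ in edges for g in (a, b)})
    return DifferentialNetwork(nodes=nodes, edges=edges, min_score=min_score, T=imp.T)


def find_hubs(net: DifferentialNetwork, min_degree: int = 4) -> list[str]:
    """Genes with degree >= min_degree in the retained edge set,
    sorted by degree descending (ties lexicographic)."""
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    deg = net.degree()
    hubs = [n for n, d in deg.items() if d >= min_degree]
    return sorted(hubs, key=lambda n: (-deg[n], n))
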