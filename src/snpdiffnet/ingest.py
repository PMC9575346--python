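"""Genotype ingestion and gene-level risk scores.

Genotypes are additive minor/alternate-allele counts (0/1/2) for a
case–control cohort, read either from a delimited text table or from a
VCF with a companion sample table. SNPs are aggregated to gene-level
risk scores: the per-sample mean of the additive codes over all SNPs
mapped to a gene.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SnpGeneMap",
    "GeneScoreMatrix",
    "read_genotypes",
    "read_snp_gene_map",
    "compute_gene_scores",
]

RESERVED_COLUMNS = ("sample_id", "label")


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates the expected dialect."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive genotype matrix with labels and covariates.

    ``values`` holds minor/alternate-allele counts as floats so that
    missing calls can be carried as NaN; every non-missing entry is in
    {0, 1, 2}. ``y`` is the binary phenotype (1 = case). ``covariates``
    is a samples x T numeric frame aligned with ``sample_ids``.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray
    y: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.values.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            dupes = _duplicates(self.snp_ids)
            raise ValueError(f"duplicate SNP ids: {sorted(dupes)}")
        finite = self.values[~np.isnan(self.values)]
        bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
        if bad.size:
            raise ValueError(
                f"genotype values outside {{0,1,2}}/missing: {sorted(set(bad))[:5]}"
            )
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if len(self.y) != len(self.sample_ids):
            raise ValueError("label vector length does not match samples")
        if len(self.covariates) not in (0, len(self.sample_ids)):
            raise ValueError("covariate table length does not match samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def covariate_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Return selected covariates as a float array (all by default)."""
        z = self.covariates if names is None else self.covariates[list(names)]
        return np.asarray(z, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Round-trippable delimited representation (reserved columns first)."""
        df = pd.DataFrame({"sample_id": self.sample_ids, "label": self.y})
        for c in self.covariates.columns:
            df[c] = np.asarray(self.covariates[c])
        geno = pd.DataFrame(self.values, columns=self.snp_ids)
        return pd.concat([df, geno], axis=1)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


@dataclass
class SnpGeneMap:
    """Many-to-one SNP -> gene assignment."""

    snp_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        if not self.snp_to_gene:
            raise ValueError("empty SNP-gene map")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "SnpGeneMap":
        mapping: dict[str, str] = {}
        for snp, gene in pairs:
            if snp in mapping and mapping[snp] != gene:
                raise ValueError(
                    f"SNP {snp!r} mapped to two genes: {mapping[snp]!r} and {gene!r}"
                )
            mapping[snp] = gene
        return cls(mapping)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.snp_to_gene.values():
            seen.setdefault(g)
        return list(seen)

    def snps_for(self, gene: str) -> list[str]:
        return [s for s, g in self.snp_to_gene.items() if g == gene]

    def write(self, path: str | Path, sep: str = "\t") -> None:
        pd.DataFrame(
            {"snp_id": list(self.snp_to_gene), "gene_id": list(self.snp_to_gene.values())}
        ).to_csv(path, sep=sep, index=False)


@dataclass
class GeneScoreMatrix:
    """Samples x genes matrix of per-gene mean additive scores.

    Each score is the arithmetic mean of 0/1/2 codes, hence lies in
    [0, 2] (NaN where a score could not be formed).
    """

    sample_ids: list[str]
    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("score matrix shape mismatch")
        finite = self.scores[~np.isnan(self.scores)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("gene scores must lie in [0, 2]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def column(self, gene: str) -> np.ndarray:
        return self.scores[:, self.gene_ids.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.gene_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    return {x for x in items if x in seen or seen.add(x)}


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in head else ","


def _read_sample_table(
    path: Path, covariates: Sequence[str] | None
) -> tuple[pd.DataFrame, list[str]]:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    for col in RESERVED_COLUMNS:
        if col not in df.columns:
            raise GenotypeParseError(f"{path}: missing reserved column {col!r}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in RESERVED_COLUMNS]
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise GenotypeParseError(f"{path}: covariate columns not found: {missing}")
    return df, list(covariates)


def _read_delimited(path: Path, covariates: Sequence[str] | None) -> GenotypeMatrix:
    sep = _sniff_sep(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = next(csv.reader(io.StringIO(fh.readline()), delimiter=sep))
    dupes = _duplicates(header)
    if dupes:
        raise GenotypeParseError(f"{path}: duplicated column ids {sorted(dupes)}")
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    for col in RESERVED_COLUMNS:
        if col not in df.columns:
            raise GenotypeParseError(f"{path}: missing reserved column {col!r}")
    if covariates is None:
        covariates = []
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise GenotypeParseError(f"{path}: covariate columns not found: {missing}")
    snp_cols = [c for c in df.columns if c not in RESERVED_COLUMNS and c not in covariates]
    if not snp_cols:
        raise GenotypeParseError(f"{path}: no SNP columns found")
    values = df[snp_cols].to_numpy(dtype=float)
    bad = np.argwhere(~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))))
    if bad.size:
        r, c = bad[0]
        raise GenotypeParseError(
            f"{path}: value {values[r, c]!r} outside {{0,1,2}}/missing at "
            f"sample {df['sample_id'].iloc[r]!r}, SNP {snp_cols[c]!r}"
        )
    if df["sample_id"].duplicated().any():
        dupes2 = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise GenotypeParseError(f"{path}: duplicate sample ids {sorted(set(dupes2))}")
    return GenotypeMatrix(
        sample_ids=df["sample_id"].tolist(),
        snp_ids=snp_cols,
        values=values,
        y=df["label"].to_numpy(dtype=int),
        covariates=df[list(covariates)].reset_index(drop=True),
    )


def _read_vcf(
    path: Path, sample_table: Path, covariates: Sequence[str] | None
) -> GenotypeMatrix:
    from cyvcf2 import VCF

    meta, covariates = _read_sample_table(sample_table, covariates)
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        codes = np.full(len(vcf_samples), np.nan)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]  # trailing element is phasing flag
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                continue  # half-call / missing / non-diploid -> missing
            codes[i] = float(sum(1 for a in alleles if a > 0))
        snp_ids.append(snp_id)
        rows.append(codes)
    vcf.close()
    if _duplicates(snp_ids):
        raise GenotypeParseError(f"{path}: duplicated variant ids {sorted(_duplicates(snp_ids))}")
    values = np.column_stack(rows) if rows else np.empty((len(vcf_samples), 0))
    meta = meta.set_index("sample_id")
    missing = [s for s in vcf_samples if s not in meta.index]
    if missing:
        raise GenotypeParseError(
            f"{sample_table}: no phenotype row for VCF samples {missing[:5]}"
        )
    meta = meta.loc[vcf_samples]
    return GenotypeMatrix(
        sample_ids=vcf_samples,
        snp_ids=snp_ids,
        values=values,
        y=meta["label"].to_numpy(dtype=int),
        covariates=meta[list(covariates)].reset_index(drop=True),
    )


def read_genotypes(
    path: str | Path,
    dialect: Literal["delimited", "vcf"] = "delimited",
    *,
    sample_table: str | Path | None = None,
    covariates: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from disk.

    Parameters
    ----------
    path:
        Delimited table (header of SNP ids plus reserved ``sample_id`` /
        ``label`` columns, one row per sample) or a VCF file.
    dialect:
        ``"delimited"`` or ``"vcf"``. The VCF dialect converts GT fields
        to alternate-allele counts; half-calls and non-diploid calls
        become missing, and labels/covariates come from ``sample_table``.
    sample_table:
        Companion delimited table for the VCF dialect with ``sample_id``,
        ``label`` and covariate columns.
    covariates:
        Covariate column names. ``None`` means no covariates for the
        delimited dialect and all non-reserved columns for the companion
        sample table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "delimited":
        return _read_delimited(path, covariates)
    if dialect == "vcf":
        if sample_table is None:
            raise GenotypeParseError(
                "the VCF dialect requires a companion sample table with labels"
            )
        return _read_vcf(path, Path(sample_table), covariates)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_snp_gene_map(path: str | Path) -> SnpGeneMap:
    """Read a 2-column (snp_id, gene_id) delimited file."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    if df.shape[1] < 2:
        raise GenotypeParseError(f"{path}: expected 2 columns (snp_id, gene_id)")
    return SnpGeneMap.from_pairs(list(zip(df.iloc[:, 0], df.iloc[:, 1])))


def compute_gene_scores(
    g: GenotypeMatrix,
    m: SnpGeneMap | Mapping[str, str],
    missing_policy: Literal["per_snp_mean_impute", "drop_from_mean"] = "per_snp_mean_impute",
) -> GeneScoreMatrix:
    """Aggregate SNP genotypes to per-gene risk scores.

    The score for (sample, gene) is the arithmetic mean of the sample's
    additive codes over the gene's SNPs. Under ``per_snp_mean_impute``
    (the default) a missing genotype is replaced by that SNP's sample
    mean before averaging, which keeps every sample usable for bivariate
    density estimation; under ``drop_from_mean`` the mean is taken over
    the sample's non-missing SNPs only.
    """
    if not isinstance(m, SnpGeneMap):
        m = SnpGeneMap(dict(m))
    if missing_policy not in ("per_snp_mean_impute", "drop_from_mean"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    snp_index = {s: k for k, s in enumerate(g.snp_ids)}
    genes = m.genes
    scores = np.full((g.n_samples, len(genes)), np.nan)
    values = g.values
    if missing_policy == "per_snp_mean_impute":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            col_means = np.nanmean(values, axis=0)
        values = np.where(np.isnan(values), col_means, values)
    for j, gene in enumerate(genes):
        cols = [snp_index[s] for s in m.snps_for(gene) if s in snp_index]
        if not cols:
            raise ValueError(f"gene {gene!r}: none of its SNPs are present in the genotypes")
        block = values[:, cols]
        n_obs = np.sum(~np.isnan(block), axis=1)
        if (n_obs == 0).any():
            k = int(np.argmax(n_obs == 0))
            warnings.warn(
                f"gene {gene!r}: sample {g.sample_ids[k]!r} has no usable "
                "genotype; score set to missing",
                stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scores[:, j] = np.nanmean(block, axis=1)
    return GeneScoreMatrix(sample_ids=list(g.sample_ids), gene_ids=genes, scores=scores)
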