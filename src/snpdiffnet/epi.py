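"""Demographic case–control tables and Pearson chi-square tests.

Builds Table-1-style cross-tabulations of categorical (or binned
numeric) factors against case status and tests independence with the
uncorrected Pearson chi-square statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = ["ContingencyTable", "crosstab", "chisq_independence", "epi_report"]


@dataclass
class ContingencyTable:
    """r x 2 cross-tabulation of a factor by class (columns control, case)."""

    factor_name: str
    row_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("counts must be an r x 2 matrix (control, case)")
        if self.counts.shape[0] != len(self.row_labels):
            raise ValueError("row label count mismatch")
        if self.counts.shape[0] < 2:
            raise ValueError("need at least 2 factor categories")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError("both class columns need a positive total")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=["control", "case"])
        df.insert(0, "category", self.row_labels)
        return df


class ChisqResult(NamedTuple):
    statistic: float
    df: int
    p: float


def _bin_labels(bins: Sequence[float]) -> list[str]:
    labels = [f"<={bins[0]:g}"]
    labels += [f"{lo:g}<x<={hi:g}" for lo, hi in zip(bins[:-1], bins[1:])]
    labels.append(f">{bins[-1]:g}")
    return labels


def crosstab(
    values: Sequence,
    labels: Sequence[int],
    bins: Sequence[float] | None = None,
    factor_name: str = "factor",
) -> ContingencyTable:
    """Cross-tabulate a per-sample factor against the binary class label.

    Numeric factors are binned at ``bins`` into right-closed intervals
    (x <= c1, c1 < x <= c2, ..., > cm), matching the "<= 28 / > 28"
    dichotomies conventional in case–control demographics tables.
    Samples with a missing factor value are dropped, so each factor is
    tabulated on its own non-missing subset.
    """
    values = pd.Series(values)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must have the same length")
    if len(values) == 0:
        raise ValueError("empty input")
    keep = ~values.isna().to_numpy()
    values, labels = values[keep], labels[keep]
    if len(values) == 0:
        raise ValueError("no non-missing observations")
    if bins is not None:
        bins = list(bins)
        if any(b2 <= b1 for b1, b2 in zip(bins[:-1], bins[1:])):
            raise ValueError("bins must be strictly increasing")
        edges = [-np.inf, *bins, np.inf]
        cats = pd.cut(values.astype(float), edges, right=True, labels=_bin_labels(bins))
        row_order = list(cats.cat.categories)
        cats = cats.astype(str)
    else:
        cats = values.astype(str)
        row_order = sorted(pd.unique(cats))
    counts = []
    kept_labels = []
    for lab in row_order:
        row = [int(np.sum((cats == lab) & (labels == 0))), int(np.sum((cats == lab) & (labels == 1)))]
        if sum(row) == 0:
            warnings.warn(f"{factor_name}: category {lab!r} has zero count, dropped", stacklevel=2)
            continue
        kept_labels.append(str(lab))
        counts.append(row)
    return ContingencyTable(factor_name=factor_name, row_labels=kept_labels, counts=np.array(counts))


def chisq_independence(table: ContingencyTable) -> ChisqResult:
    """Pearson chi-square test of factor/class independence.

    No continuity correction is applied, including for 2x2 tables;
    expected counts are row_total * col_total / grand_total and the
    p-value is the upper tail of the chi-square distribution on
    (r-1)(c-1) degrees of freedom.
    """
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError(f"{table.factor_name}: zero marginal total gives zero expected counts")
    res = chi2_contingency(counts, correction=False)
    return ChisqResult(statistic=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


def epi_report(
    covariates: pd.DataFrame,
    labels: Sequence[int],
    bins: dict[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Chi-square screen of every covariate against case status.

    Continuous covariates must appear in ``bins`` (cut points); columns
    with few distinct values are treated as categorical. Returns one row
    per factor/category with counts, percentages, and the factor-level
    statistic and p-value (printed to 3 decimals in the formatted
    columns; full precision in ``statistic``/``p``).
    """
    bins = bins or {}
    labels = np.asarray(labels)
    rows = []
    for name in covariates.columns:
        vals = covariates[name]
        table = crosstab(vals, labels, bins=bins.get(name), factor_name=name)
        res = chisq_independence(table)
        col_tot = table.counts.sum(axis=0)
        for i, cat in enumerate(table.row_labels):
            n_ctl, n_case = table.counts[i]
            rows.append(
                {
                    "factor": name,
                    "category": cat,
                    "control_n": n_ctl,
                    "control_pct": round(100 * n_ctl / col_tot[0], 2),
                    "case_n": n_case,
                    "case_pct": round(100 * n_case / col_tot[1], 2),
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p,
                    "statistic_3dp": f"{res.statistic:.3f}",
                    "p_3dp": f"{res.p:.3f}",
                }
            )
    return pd.DataFrame(rows)
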