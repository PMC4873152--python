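"""Differential-expression surrogate testing and the upregulation filter.

The screen consumes islet expression either as a normalized gene-by-sample
matrix with a two-level disease grouping (ND vs T2D) or as precomputed
per-gene statistics from an upstream engine. The in-package surrogate test
is deliberately simple: an unpaired t test on log2(x+1) values or a
rank-sum test on raw values, with the fold change reported on the log2
scale and oriented so that positive means higher in disease.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "FilterResult",
    "CorrelationResult",
    "de_test",
    "filter_upregulated",
    "covariate_correlation",
    "results_from_table",
    "adjust_pvalues",
]

GROUPS = ("ND", "T2D")
DE_METHODS = ("t_log2", "ranksum")
MT_PROCEDURES = ("none", "BH", "bonferroni")
CORR_METHODS = ("spearman", "pearson")


@dataclass
class ExpressionMatrix:
    """Non-negative expression levels (genes x samples) with a group label.

    ``values`` rows are gene ids, columns sample ids; ``group`` maps each
    sample to "ND" or "T2D". Missing values must be resolved upstream.
    """

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids in expression matrix: {dupes}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        missing = [s for s in self.values.columns if s not in self.group.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.group = self.group.loc[self.values.columns]
        bad = sorted(set(self.group) - set(GROUPS))
        if bad:
            raise ValueError(f"group labels must be in {GROUPS}, got {bad}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("expression matrix contains missing values")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    def group_columns(self, label: str) -> pd.DataFrame:
        return self.values.loc[:, self.group[self.group == label].index]


@dataclass
class DEResult:
    """Per-gene differential-expression statistics (T2D relative to ND)."""

    gene_id: str
    log2fc: float
    p_value: float
    p_adj: float | None = None
    source: str = "computed"
    degenerate: bool = False


def de_test(matrix: ExpressionMatrix, method: str = "t_log2") -> list[DEResult]:
    """Two-group test per gene; fold change on the log2 scale, T2D minus ND.

    ``t_log2`` applies an unpaired pooled-variance t test to log2(x+1)
    transformed values; ``ranksum`` a Mann-Whitney test to raw values.
    Genes with zero variance in both groups are degenerate: they receive
    p = 1 by convention and are flagged.
    """
    if method not in DE_METHODS:
        raise ValueError(f"DE method must be one of {DE_METHODS}, got {method!r}")
    case = matrix.group_columns("T2D").to_numpy(dtype=float)
    control = matrix.group_columns("ND").to_numpy(dtype=float)
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError(
            "both groups need >= 2 samples for differential expression "
            f"(got T2D={case.shape[1]}, ND={control.shape[1]})"
        )
    log_case = np.log2(case + 1.0)
    log_control = np.log2(control + 1.0)
    log2fc = log_case.mean(axis=1) - log_control.mean(axis=1)
    degenerate = (log_case.var(axis=1) == 0) & (log_control.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "t_log2":
            _, p = stats.ttest_ind(log_case, log_control, axis=1, equal_var=True)
        else:
            _, p = stats.mannwhitneyu(
                case, control, axis=1, alternative="two-sided"
            )
    p = np.asarray(p, dtype=float)
    p[degenerate] = 1.0
    p[np.isnan(p)] = 1.0  # residual ties / zero-spread cases
    return [
        DEResult(
            gene_id=g,
            log2fc=float(fc),
            p_value=float(pv),
            source="computed",
            degenerate=bool(dg),
        )
        for g, fc, pv, dg in zip(matrix.genes, log2fc, p, degenerate)
    ]


def adjust_pvalues(p_values: Sequence[float], procedure: str) -> np.ndarray:
    """Multiple-testing adjustment: none, Benjamini-Hochberg or Bonferroni."""
    if procedure not in MT_PROCEDURES:
        raise ValueError(
            f"procedure must be one of {MT_PROCEDURES}, got {procedure!r}"
        )
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0 or procedure == "none":
        return arr.copy()
    method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}[procedure]
    return multipletests(arr, method=method)[1]


class FilterResult(NamedTuple):
    """Outcome of the upregulation filter over a candidate set."""

    passed: frozenset
    missing: frozenset
    table: pd.DataFrame


def filter_upregulated(
    results: Iterable[DEResult],
    candidates: Iterable[str],
    alpha: float = 0.05,
    procedure: str = "none",
) -> FilterResult:
    """Candidate genes significantly higher in disease.

    Retains candidates with positive log2 fold change and (adjusted)
    ``p < alpha``; adjustment is applied across the candidate genes
    present in ``results``. Candidates absent from the results are
    reported in ``missing``, never silently dropped. Deterministic and
    independent of input ordering.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    by_gene = {r.gene_id: r for r in results}
    candidate_ids = set(candidates)
    missing = frozenset(candidate_ids - set(by_gene))
    present = sorted(candidate_ids & set(by_gene))
    rows = [by_gene[g] for g in present]
    p_adj = adjust_pvalues([r.p_value for r in rows], procedure)
    table = pd.DataFrame(
        {
            "gene_id": present,
            "log2fc": [r.log2fc for r in rows],
            "p_value": [r.p_value for r in rows],
            "p_adj": p_adj,
            "source": [r.source for r in rows],
        }
    ).set_index("gene_id")
    table["passed"] = (table["log2fc"] > 0) & (table["p_adj"] < alpha)
    passed = frozenset(table.index[table["passed"]])
    return FilterResult(passed=passed, missing=missing, table=table)


class CorrelationResult(NamedTuple):
    coefficient: float
    p_value: float
    n_used: int
    n_dropped: int


def covariate_correlation(
    expr: Sequence[float],
    covariate: Sequence[float],
    method: str = "spearman",
) -> CorrelationResult:
    """Correlate one gene's expression with a continuous clinical covariate.

    Pairs with a missing covariate (or expression) value are removed and
    counted. Constant vectors make the coefficient undefined and raise.
    """
    if method not in CORR_METHODS:
        raise ValueError(
            f"correlation method must be one of {CORR_METHODS}, got {method!r}"
        )
    x = np.asarray(expr, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expression and covariate vectors differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    n_dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError(
            f"need >= 4 complete pairs for a correlation, got {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        coef, p = stats.spearmanr(x, y)
    else:
        coef, p = stats.pearsonr(x, y)
    return CorrelationResult(
        coefficient=float(coef),
        p_value=float(p),
        n_used=int(x.size),
        n_dropped=n_dropped,
    )


def results_from_table(table: pd.DataFrame) -> list[DEResult]:
    """Wrap a precomputed per-gene statistics table as DE results.

    Expects columns ``gene_id``, ``log2fc``, ``p_value`` and optionally
    ``p_adj``; rows pass through the filters identically to computed
    results with equal values.
    """
    required = {"gene_id", "log2fc", "p_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"precomputed DE table lacks columns: {sorted(missing)}")
    has_adj = "p_adj" in table.columns
    return [
        DEResult(
            gene_id=str(row.gene_id),
            log2fc=float(row.log2fc),
            p_value=float(row.p_value),
            p_adj=float(row.p_adj) if has_adj and pd.notna(row.p_adj) else None,
            source="precomputed",
        )
        for row in table.itertuples(index=False)
    ]
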