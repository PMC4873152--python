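"""Infinium-style methylation handling for per-gene probe panels.

Covers the corroboration layer of the screen: detection-P based probe
exclusion, the logit2 transform between beta-values and M-values
(``M = log2(beta / (1 - beta))``), covariate-adjusted per-site linear
models of methylation on expression, flagging of significant negative
methylation-expression sites, and group (ND vs T2D) methylation
differences on either the beta-percent or M scale.

Statistics are computed on M-values, which are approximately
homoscedastic; beta-values remain the reporting scale because a
methylation fraction is the biologically interpretable quantity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenotype import SummaryStat, two_group_test_from_summary

__all__ = [
    "MethylationMatrix",
    "SiteAssociation",
    "DetectionFilterResult",
    "beta_to_m",
    "m_to_beta",
    "detection_filter",
    "site_expression_association",
    "flag_negative_sites",
    "group_methylation_difference",
    "expand_covariates",
    "BETA_CLAMP_EPS",
]

BETA_CLAMP_EPS = 1e-6  # reader-boundary clamp for beta in {0, 1}
DIFFERENCE_SCALES = ("beta_percent", "m_value")


def beta_to_m(beta):
    """Logit2 transform of methylation fractions: ``M = log2(b / (1 - b))``.

    Strictly increasing; accepts scalars or arrays. Values outside the
    open interval (0, 1) are rejected -- clamping is a reader-boundary
    policy, never applied silently here.
    """
    arr = np.asarray(beta, dtype=float)
    if not np.all((arr > 0) & (arr < 1)):
        raise ValueError("beta-values must lie strictly inside (0, 1)")
    out = np.log2(arr / (1.0 - arr))
    return float(out) if np.isscalar(beta) else out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: ``beta = 2**M / (1 + 2**M)``."""
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    return float(out) if np.isscalar(m) else out


@dataclass
class MethylationMatrix:
    """Beta-values, detection P-values and grouping for a probe panel.

    ``beta`` and ``detection_p`` are probe-by-sample frames with matching
    axes; ``group`` labels each sample "ND" or "T2D". ``manifest``
    optionally assigns probes to genes and genomic positions (columns
    ``gene_id``, ``chrom``, ``position``; indexed by probe id).
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    group: pd.Series
    manifest: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            raise ValueError("duplicate probe ids in methylation matrix")
        if not self.beta.index.equals(self.detection_p.index) or not (
            self.beta.columns.equals(self.detection_p.columns)
        ):
            raise ValueError(
                "beta and detection-P matrices must share probe and sample axes"
            )
        missing = [s for s in self.beta.columns if s not in self.group.index]
        if missing:
            raise ValueError(f"methylation samples without a group label: {missing}")
        self.group = self.group.loc[self.beta.columns]
        arr = self.beta.to_numpy(dtype=float)
        if not np.all((arr > 0) & (arr < 1)):
            raise ValueError(
                "beta-values must be strictly inside (0, 1); clamp boundary "
                "values when reading the matrix"
            )
        darr = self.detection_p.to_numpy(dtype=float)
        if not np.all((darr >= 0) & (darr <= 1)):
            raise ValueError("detection P-values must lie in [0, 1]")

    @property
    def probes(self) -> list[str]:
        return self.beta.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.beta.columns.tolist()

    def m_values(self) -> pd.DataFrame:
        return pd.DataFrame(
            beta_to_m(self.beta.to_numpy(dtype=float)),
            index=self.beta.index,
            columns=self.beta.columns,
        )

    def subset(self, probes: Sequence[str]) -> "MethylationMatrix":
        manifest = (
            self.manifest.loc[self.manifest.index.intersection(probes)]
            if self.manifest is not None
            else None
        )
        return MethylationMatrix(
            beta=self.beta.loc[list(probes)],
            detection_p=self.detection_p.loc[list(probes)],
            group=self.group,
            manifest=manifest,
        )


class DetectionFilterResult(NamedTuple):
    matrix: MethylationMatrix
    removed: tuple
    mean_detection_p: pd.Series


def detection_filter(
    matrix: MethylationMatrix, threshold: float = 0.01
) -> DetectionFilterResult:
    """Drop probes whose mean detection P across samples exceeds the cutoff.

    The comparison is a strict ``>``: a probe at exactly the threshold is
    retained. Idempotent; removed probe ids are reported. An empty
    surviving panel is allowed (with all probes listed as removed) so the
    caller can report it, but no statistics can be computed downstream.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"detection threshold must be in (0, 1), got {threshold}")
    mean_p = matrix.detection_p.mean(axis=1)
    keep = mean_p.index[mean_p <= threshold].tolist()
    removed = tuple(p for p in matrix.probes if p not in set(keep))
    return DetectionFilterResult(
        matrix=matrix.subset(keep), removed=removed, mean_detection_p=mean_p
    )


@dataclass
class SiteAssociation:
    """Per-probe linear association between methylation (M) and expression."""

    probe_id: str
    slope: float
    stderr: float
    p_value: float
    flagged_negative: bool = False

    @property
    def direction(self) -> int:
        return 0 if self.slope == 0 else (1 if self.slope > 0 else -1)


def expand_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand categorical covariate columns to indicator contrasts.

    Object/category/bool columns (e.g. batch, gender) become 0/1 dummy
    columns with the first level as reference; numeric columns (BMI, age,
    islet purity, days of culture) pass through unchanged.
    """
    if covariates.empty:
        return covariates.copy()
    expanded = pd.get_dummies(covariates, drop_first=True, dtype=float)
    return expanded.astype(float)


def _check_full_rank(design: pd.DataFrame) -> None:
    arr = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # QR with column pivoting: the trailing pivots index dependent columns.
        from scipy.linalg import qr

        _, _, pivots = qr(arr, pivoting=True)
        dependent = sorted(design.columns[i] for i in pivots[rank:])
        raise ValueError(
            "rank-deficient regression design; collinear columns: "
            + ", ".join(map(str, dependent))
        )


def site_expression_association(
    matrix: MethylationMatrix,
    expression: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> list[SiteAssociation]:
    """OLS of per-probe M-values on focal-gene expression plus covariates.

    ``expression`` and ``covariates`` must cover exactly the matrix's
    samples. The reported slope, standard error and two-sided p-value
    belong to the expression coefficient; with no covariates the fit
    reduces to simple linear regression. A negative slope means
    methylation falls as expression rises.
    """
    samples = matrix.samples
    if set(expression.index) != set(samples):
        raise ValueError(
            "expression sample ids do not match the methylation matrix"
        )
    design = pd.DataFrame({"expression": expression.loc[samples].astype(float)})
    if covariates is not None and not covariates.empty:
        if set(covariates.index) != set(samples):
            raise ValueError(
                "covariate sample ids do not match the methylation matrix"
            )
        design = pd.concat(
            [design, expand_covariates(covariates.loc[samples])], axis=1
        )
    design = sm.add_constant(design, prepend=True)
    n_params = design.shape[1]
    if len(samples) <= n_params + 1:
        raise ValueError(
            f"n = {len(samples)} samples is too small for {n_params} "
            "regression parameters"
        )
    _check_full_rank(design)
    m_values = matrix.m_values()
    out: list[SiteAssociation] = []
    exog = design.to_numpy(dtype=float)
    expr_idx = design.columns.get_loc("expression")
    for probe in matrix.probes:
        fit = sm.OLS(m_values.loc[probe].to_numpy(dtype=float), exog).fit()
        out.append(
            SiteAssociation(
                probe_id=probe,
                slope=float(fit.params[expr_idx]),
                stderr=float(fit.bse[expr_idx]),
                p_value=float(fit.pvalues[expr_idx]),
            )
        )
    return out


def flag_negative_sites(
    assocs: Sequence[SiteAssociation],
    alpha: float = 0.05,
    procedure: str = "bonferroni",
) -> frozenset:
    """Probes with a significant negative methylation-expression slope.

    Multiple testing is handled within the panel (default Bonferroni at
    family level ``alpha``, i.e. per-site threshold ``alpha / n_probes``).
    Flagged probes are also marked in place via ``flagged_negative``.
    """
    from .expression import adjust_pvalues

    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not assocs:
        return frozenset()
    p_adj = adjust_pvalues([a.p_value for a in assocs], procedure)
    flagged = set()
    for assoc, adj in zip(assocs, p_adj):
        hit = assoc.slope < 0 and adj < alpha
        assoc.flagged_negative = bool(hit)
        if hit:
            flagged.add(assoc.probe_id)
    return frozenset(flagged)


class GroupDifference(NamedTuple):
    probe_id: str
    delta: float
    p_value: float


def group_methylation_difference(
    data: "MethylationMatrix | Mapping[str, tuple[SummaryStat, SummaryStat]]",
    scale: str = "beta_percent",
    variant: str = "student_pooled",
) -> pd.DataFrame:
    """Per-probe ND-vs-T2D methylation difference with a two-sided p-value.

    ``delta`` is the ND group mean minus the T2D group mean, so a positive
    value is a methylation loss in disease. On the ``beta_percent`` scale
    deltas are percentage points of mean beta x 100; ``m_value`` reports
    the difference of group mean M-values. Input is either a full matrix
    or, when only published summaries are available, a mapping of probe id
    to an (ND, T2D) pair of :class:`~aneuscreen.phenotype.SummaryStat`
    already on the requested scale.
    """
    if scale not in DIFFERENCE_SCALES:
        raise ValueError(f"scale must be one of {DIFFERENCE_SCALES}, got {scale!r}")
    rows: list[GroupDifference] = []
    if isinstance(data, MethylationMatrix):
        values = data.beta * 100.0 if scale == "beta_percent" else data.m_values()
        nd_samples = data.group[data.group == "ND"].index
        t2d_samples = data.group[data.group == "T2D"].index
        if len(nd_samples) < 2 or len(t2d_samples) < 2:
            raise ValueError("both groups need >= 2 methylation samples")
        for probe in data.probes:
            nd = SummaryStat.from_values(values.loc[probe, nd_samples])
            t2d = SummaryStat.from_values(values.loc[probe, t2d_samples])
            res = two_group_test_from_summary(nd, t2d, variant=variant)
            rows.append(GroupDifference(probe, nd.mean - t2d.mean, res.p_value))
    else:
        for probe, (nd, t2d) in data.items():
            res = two_group_test_from_summary(nd, t2d, variant=variant)
            rows.append(GroupDifference(probe, nd.mean - t2d.mean, res.p_value))
    return pd.DataFrame(rows).set_index("probe_id")
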