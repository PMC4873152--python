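"""The screen funnel: phenotypes -> region -> DE -> methylation -> ranking.

``run_screen`` stitches the layer modules together into one deterministic
pass and emits an evidence table with one row per in-region candidate
gene. Layers beyond the region are either *required* (a gene must pass to
survive) or *corroborative* (recorded but not gating); the default
requires region and differential expression, with methylation
corroborative. The final manual-prioritisation step of a screen of this
kind is represented only as an optional user-supplied per-gene annotation
flag -- the pipeline never infers it.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .expression import (
    DEResult,
    ExpressionMatrix,
    de_test,
    filter_upregulated,
)
from .intervals import AneuploidyModel, GeneRecord, SyntenyMap, candidate_gene_set
from .methylation import (
    MethylationMatrix,
    detection_filter,
    flag_negative_sites,
    site_expression_association,
)
from .phenotype import PhenotypeCall, SummaryStat, classify_glycaemia

__all__ = ["ScreenConfig", "ScreenError", "ScreenReport", "run_screen", "rank_candidates"]

LAYERS = ("region", "de", "methylation", "annotation")


class ScreenError(RuntimeError):
    """A layer failure that aborts the screen, carrying completed layers."""

    def __init__(self, message: str, completed_layers: tuple = ()):
        super().__init__(message)
        self.completed_layers = completed_layers


@dataclass(frozen=True)
class ScreenConfig:
    """All tunable screen parameters with reproduction-oriented defaults."""

    alpha_phenotype: float = 0.05
    alpha_de: float = 0.05
    alpha_methylation: float = 0.05
    test_variant: str = "student_pooled"
    containment: str = "full"
    ortholog_policy: str = "one_to_one_only"
    de_method: str = "t_log2"
    de_procedure: str = "none"
    methylation_procedure: str = "bonferroni"
    detection_threshold: float = 0.01
    adjust_methylation_covariates: bool = True
    affected_label: str = "hyperglycaemic"
    required_layers: tuple[str, ...] = ("region", "de")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_phenotype", "alpha_de", "alpha_methylation"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {value}")
        object.__setattr__(self, "required_layers", tuple(self.required_layers))
        unknown = set(self.required_layers) - set(LAYERS)
        if unknown:
            raise ValueError(f"unknown required layers: {sorted(unknown)}")
        if "region" not in self.required_layers:
            raise ValueError("required_layers must always include 'region'")

    @classmethod
    def from_json(cls, text: str) -> "ScreenConfig":
        data = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["required_layers"] = list(self.required_layers)
        return d


@dataclass
class ScreenReport:
    """Ranked per-gene evidence plus per-layer counts and provenance."""

    table: pd.DataFrame
    ranked: list[str]
    phenotypes: dict[str, PhenotypeCall]
    layer_counts: dict[str, int]
    config: ScreenConfig
    side: dict
    provenance: dict

    @property
    def final_pass(self) -> frozenset:
        return frozenset(self.table.index[self.table["final_pass"]])


EVIDENCE_COLUMNS = [
    "in_region",
    "de_log2fc",
    "de_p",
    "de_p_adj",
    "de_pass",
    "meth_n_probes",
    "meth_flagged",
    "meth_status",
    "meth_pass",
    "annotation_flag",
    "layers_passed",
    "final_pass",
]


def _resolve_phenotypes(
    models: Sequence[AneuploidyModel],
    phenotype_data: Mapping,
    config: ScreenConfig,
) -> tuple[list[AneuploidyModel], dict[str, PhenotypeCall]]:
    """Attach a glycaemia call to every model.

    ``phenotype_data`` maps model name to either a (case, control) pair of
    :class:`SummaryStat` or a pair of raw per-animal value sequences,
    which are summarized first (the t test on summaries is identical to
    the raw-data test).
    """
    calls: dict[str, PhenotypeCall] = {}
    classified = []
    for model in models:
        if model.name not in phenotype_data:
            raise ScreenError(f"no phenotype data for model {model.name!r}")
        case, control = phenotype_data[model.name]
        if not isinstance(case, SummaryStat):
            case = SummaryStat.from_values(case)
        if not isinstance(control, SummaryStat):
            control = SummaryStat.from_values(control)
        call = classify_glycaemia(
            case, control, alpha=config.alpha_phenotype, variant=config.test_variant
        )
        calls[model.name] = call
        classified.append(model.with_phenotype(call))
    return classified, calls


def run_screen(
    config: ScreenConfig,
    models: Sequence[AneuploidyModel],
    phenotype_data: Mapping,
    annotations: Sequence[GeneRecord],
    synteny: SyntenyMap,
    expression: ExpressionMatrix | None = None,
    de_results: Sequence[DEResult] | None = None,
    methylation: MethylationMatrix | None = None,
    methylation_expression: pd.DataFrame | None = None,
    methylation_covariates: pd.DataFrame | None = None,
    annotation_flags: Mapping[str, bool] | None = None,
    input_digests: Mapping[str, str] | None = None,
) -> ScreenReport:
    """Execute the full funnel and return a ranked evidence report.

    Expression evidence comes from either a matrix (tested in-package) or
    precomputed per-gene results -- exactly one must be given. Methylation
    input is optional; when present, each candidate gene with probes in
    the matrix manifest is tested for negative methylation-expression
    sites using that gene's row of ``methylation_expression``. Genes
    without probes are marked ``no_data`` and fail the methylation layer
    only if that layer is required. Deterministic given identical inputs.
    """
    completed: list[str] = []

    # phenotype + region layer
    classified, calls = _resolve_phenotypes(models, phenotype_data, config)
    try:
        region = candidate_gene_set(
            classified,
            annotations,
            synteny,
            affected_label=config.affected_label,
            containment=config.containment,
        )
    except ValueError as exc:
        raise ScreenError(str(exc), completed_layers=tuple(completed)) from exc
    completed.append("region")
    candidates = sorted(region.genes)

    # differential-expression layer
    if (expression is None) == (de_results is None):
        raise ScreenError(
            "provide exactly one of an expression matrix or precomputed DE results",
            completed_layers=tuple(completed),
        )
    results = (
        de_test(expression, method=config.de_method)
        if expression is not None
        else list(de_results)
    )
    de = filter_upregulated(
        results, candidates, alpha=config.alpha_de, procedure=config.de_procedure
    )
    completed.append("de")

    # methylation layer (only genes with probes can be tested)
    meth_flagged: dict[str, frozenset] = {}
    meth_probes: dict[str, int] = {}
    removed_probes: tuple = ()
    if methylation is not None:
        if methylation.manifest is None:
            raise ScreenError(
                "methylation matrix lacks a probe manifest (probe -> gene map)",
                completed_layers=tuple(completed),
            )
        if methylation_expression is None:
            raise ScreenError(
                "methylation input requires per-gene expression over the "
                "methylation samples",
                completed_layers=tuple(completed),
            )
        filtered = detection_filter(methylation, threshold=config.detection_threshold)
        removed_probes = filtered.removed
        matrix = filtered.matrix
        covariates = (
            methylation_covariates if config.adjust_methylation_covariates else None
        )
        for gene in candidates:
            probe_ids = matrix.manifest.index[
                matrix.manifest["gene_id"] == gene
            ].tolist()
            if not probe_ids or gene not in methylation_expression.index:
                continue
            panel = matrix.subset(probe_ids)
            assocs = site_expression_association(
                panel,
                methylation_expression.loc[gene],
                covariates=covariates,
            )
            meth_probes[gene] = len(probe_ids)
            meth_flagged[gene] = flag_negative_sites(
                assocs,
                alpha=config.alpha_methylation,
                procedure=config.methylation_procedure,
            )
        completed.append("methylation")

    # evidence table
    flags = dict(annotation_flags or {})
    rows = []
    for gene in candidates:
        de_row = de.table.loc[gene] if gene in de.table.index else None
        n_probes = meth_probes.get(gene, 0)
        has_meth = gene in meth_flagged
        meth_pass = bool(meth_flagged.get(gene)) if has_meth else False
        entry = {
            "gene_id": gene,
            "in_region": True,
            "de_log2fc": float(de_row["log2fc"]) if de_row is not None else np.nan,
            "de_p": float(de_row["p_value"]) if de_row is not None else np.nan,
            "de_p_adj": float(de_row["p_adj"]) if de_row is not None else np.nan,
            "de_pass": bool(de_row["passed"]) if de_row is not None else False,
            "meth_n_probes": n_probes,
            "meth_flagged": len(meth_flagged.get(gene, ())),
            "meth_status": "tested" if has_meth else "no_data",
            "meth_pass": meth_pass,
            "annotation_flag": bool(flags.get(gene, False)),
        }
        layer_pass = {
            "region": True,
            "de": entry["de_pass"],
            "methylation": entry["meth_pass"],
            "annotation": entry["annotation_flag"],
        }
        entry["layers_passed"] = int(sum(layer_pass.values()))
        entry["final_pass"] = all(
            layer_pass[layer] for layer in config.required_layers
        )
        rows.append(entry)
    table = (
        pd.DataFrame(rows).set_index("gene_id").loc[:, EVIDENCE_COLUMNS]
        if rows
        else pd.DataFrame(columns=EVIDENCE_COLUMNS, index=pd.Index([], name="gene_id"))
    )
    ranked = rank_candidates(table)
    table = table.loc[ranked]

    layer_counts = {
        "region": len(candidates),
        "de": int(table["de_pass"].sum()) if len(table) else 0,
        "de_and_methylation": int((table["de_pass"] & table["meth_pass"]).sum())
        if len(table)
        else 0,
        "final": int(table["final_pass"].sum()) if len(table) else 0,
    }
    side = {
        "missing_de": sorted(de.missing),
        "dropped_orthologs": sorted(region.dropped_orthologs),
        "no_methylation_data": sorted(
            g for g in candidates if g not in meth_flagged
        )
        if methylation is not None
        else [],
        "removed_probes": sorted(removed_probes),
        "per_model_gene_counts": {
            name: len(genes) for name, genes in sorted(region.per_model.items())
        },
        "flagged_probes": {g: sorted(v) for g, v in sorted(meth_flagged.items())},
    }
    provenance = {
        "seed": config.seed,
        "version": __version__,
        "inputs": dict(input_digests or {}),
    }
    return ScreenReport(
        table=table,
        ranked=ranked,
        phenotypes=calls,
        layer_counts=layer_counts,
        config=config,
        side=side,
        provenance=provenance,
    )


def rank_candidates(table: pd.DataFrame) -> list[str]:
    """Total, stable candidate ordering.

    Sort by: number of passing layers (descending), DE p-value
    (ascending, missing last), count of flagged methylation probes
    (descending), then gene id as the lexicographic tiebreak.
    """
    if table.empty:
        return []
    keyed = table.assign(
        _p=table["de_p"].fillna(np.inf),
        _layers=-table["layers_passed"].astype(int),
        _meth=-table["meth_flagged"].astype(int),
    )
    # stable mergesort after an index sort realises gene id as final tiebreak
    ordered = keyed.sort_index(kind="mergesort").sort_values(
        by=["_layers", "_p", "_meth"], kind="mergesort"
    )
    return ordered.index.tolist()
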