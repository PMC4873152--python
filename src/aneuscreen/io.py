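"""Readers and writers for every external format, with fail-fast validation.

All genomic coordinates are stored 0-based half-open (BED convention);
GFF3 gene rows (1-based inclusive) are shifted at read time. Beta-value
matrices are validated to [0, 1] and boundary values clamped just inside
the open interval (the M transform requires it), with the clamp count
reported. Report writing is byte-stable across reruns with equal inputs:
fixed column order, fixed numeric formats, sorted JSON keys and no
timestamps.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneRecord, GenomicInterval, IntervalError, SyntenyMap
from .methylation import BETA_CLAMP_EPS
from .phenotype import SummaryStat

__all__ = [
    "Dataset",
    "MatrixPayload",
    "read_bed_segments",
    "read_gene_table",
    "read_gff3_genes",
    "read_ortholog_map",
    "read_phenotype_table",
    "read_matrix_tsv",
    "read_covariates",
    "write_report",
    "write_study",
    "sha256_digest",
    "load_dataset",
]

MATRIX_KINDS = ("expression", "beta", "detection_p")
NA_TOKEN = "NA"


class FormatError(ValueError):
    """A malformed input file; the message names the file and location."""


@dataclass(frozen=True)
class Dataset:
    """A parsed payload together with its provenance digest."""

    payload: object
    source: str
    digest: str
    schema_version: str = "1"


def sha256_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_dataset(path: str | Path, reader, **kwargs) -> Dataset:
    """Read a file through ``reader`` and record its content digest."""
    return Dataset(
        payload=reader(path, **kwargs),
        source=str(path),
        digest=sha256_digest(path),
    )


def read_bed_segments(
    path: str | Path, default_name: str | None = None
) -> list[tuple[str, GenomicInterval]]:
    """Parse BED3+ dosage segments: chrom, start, end[, model name].

    Coordinates are taken as written (0-based half-open). Malformed lines
    raise with their line number; without a fourth column the file-level
    ``default_name`` applies.
    """
    out = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        chrom, start_s, end_s = parts[0], parts[1], parts[2]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
            ) from exc
        name = parts[3] if len(parts) > 3 else default_name
        if name is None:
            raise FormatError(
                f"{path}:{lineno}: no model name column and no default name given"
            )
        try:
            interval = GenomicInterval(chrom, start, end)
        except IntervalError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        out.append((name, interval))
    return out


def write_bed_segments(
    segments: Sequence[tuple[str, GenomicInterval]], path: str | Path
) -> None:
    lines = [
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}" for name, iv in segments
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


GENE_TABLE_COLUMNS = ["gene_id", "symbol", "species", "chrom", "start", "end", "strand"]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Gene annotation TSV with 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicate gene ids {dupes}")
    records = []
    for row in df.itertuples(index=False):
        try:
            location = GenomicInterval(row.chrom, int(row.start), int(row.end))
        except (ValueError, IntervalError) as exc:
            raise FormatError(f"{path}: gene {row.gene_id}: {exc}") from exc
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                symbol=row.symbol,
                species=row.species,
                location=location,
                strand=row.strand,
            )
        )
    return records


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "symbol": g.symbol,
            "species": g.species,
            "chrom": g.location.chrom,
            "start": g.location.start,
            "end": g.location.end,
            "strand": g.strand,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gff3_genes(path: str | Path, species: str) -> list[GeneRecord]:
    """Gene features from a GFF3 subset, converted to half-open coordinates.

    Only rows with feature type ``gene`` are used; GFF3 1-based inclusive
    spans become 0-based half-open by decrementing the start. ``ID`` is
    the gene id and ``Name`` (falling back to ID) the symbol.
    """
    records = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
        chrom, _, ftype, start_s, end_s, _, strand, _, attrs = parts
        if ftype != "gene":
            continue
        attributes = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        gene_id = attributes.get("ID")
        if not gene_id:
            raise FormatError(f"{path}:{lineno}: gene feature without an ID attribute")
        try:
            start, end = int(start_s) - 1, int(end_s)
            location = GenomicInterval(chrom, start, end)
        except (ValueError, IntervalError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        records.append(
            GeneRecord(
                gene_id=gene_id,
                symbol=attributes.get("Name", gene_id),
                species=species,
                location=location,
                strand=strand if strand in ("+", "-") else "unknown",
            )
        )
    return records


def read_ortholog_map(
    path: str | Path, policy: str = "one_to_one_only"
) -> SyntenyMap:
    """Two-column TSV of (mouse gene id, human gene id); '#' comments allowed."""
    pairs = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        pairs.append((parts[0], parts[1]))
    return SyntenyMap(pairs=tuple(pairs), policy=policy)


def write_ortholog_map(synteny: SyntenyMap, path: str | Path) -> None:
    lines = ["# mouse_gene_id\thuman_gene_id"]
    lines += [f"{m}\t{h}" for m, h in synteny.pairs]
    Path(path).write_text("\n".join(lines) + "\n")


def read_phenotype_table(path: str | Path) -> dict:
    """Phenotype input TSV, per-animal or summary form.

    Summary form has columns (model, role, mean, sem, n) with role in
    {case, control}; per-animal form has (model, role, animal_id, value or
    glucose_mm). Returns ``{model: (case, control)}`` where each element
    is a :class:`SummaryStat` (summary form) or a value array.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict = {}
    if {"mean", "sem", "n"} <= set(df.columns):
        for model, sub in df.groupby("model"):
            arms = {}
            for row in sub.itertuples(index=False):
                arms[row.role] = SummaryStat(
                    mean=float(row.mean), sem=float(row.sem), n=int(row.n)
                )
            if set(arms) != {"case", "control"}:
                raise FormatError(
                    f"{path}: model {model}: need exactly one case and one "
                    "control summary row"
                )
            out[model] = (arms["case"], arms["control"])
        return out
    value_col = "glucose_mm" if "glucose_mm" in df.columns else "value"
    if not {"model", "role", value_col} <= set(df.columns):
        raise FormatError(
            f"{path}: expected summary columns (model, role, mean, sem, n) or "
            f"per-animal columns (model, role, {value_col})"
        )
    for model, sub in df.groupby("model"):
        case = sub.loc[sub["role"] == "case", value_col].to_numpy(dtype=float)
        control = sub.loc[sub["role"] == "control", value_col].to_numpy(dtype=float)
        if case.size < 2 or control.size < 2:
            raise FormatError(
                f"{path}: model {model}: both arms need >= 2 animals"
            )
        out[model] = (case, control)
    return out


class MatrixPayload(NamedTuple):
    values: pd.DataFrame
    n_clamped: int


def read_matrix_tsv(path: str | Path, kind: str) -> MatrixPayload:
    """Feature-by-sample numeric TSV (first column feature id, header row).

    The only missing-value token accepted is ``NA``. Beta matrices are
    validated to [0, 1]; cells at exactly 0 or 1 are clamped to
    ``[eps, 1 - eps]`` and counted (M-values must be finite). Duplicate
    ids, ragged rows and non-numeric cells are rejected with coordinates.
    """
    if kind not in MATRIX_KINDS:
        raise FormatError(f"matrix kind must be one of {MATRIX_KINDS}, got {kind!r}")
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or unparseable TSV: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate feature ids {dupes}")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids in header")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            feature = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric cell at feature {feature!r}, sample {col!r}"
            )
        df[col] = converted
    n_clamped = 0
    if kind == "beta":
        arr = df.to_numpy(dtype=float)
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise FormatError(f"{path}: beta-values outside [0, 1]")
        at_bound = (arr == 0.0) | (arr == 1.0)
        n_clamped = int(at_bound.sum())
        arr = np.clip(arr, BETA_CLAMP_EPS, 1.0 - BETA_CLAMP_EPS)
        df = pd.DataFrame(arr, index=df.index, columns=df.columns)
    if kind == "detection_p":
        arr = df.to_numpy(dtype=float)
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise FormatError(f"{path}: detection P-values outside [0, 1]")
    return MatrixPayload(values=df, n_clamped=n_clamped)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Per-sample covariate TSV indexed by the first column (sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids")
    return df


def _format_float(value: float) -> str:
    if pd.isna(value):
        return NA_TOKEN
    return f"{value:.6e}"


def write_report(report, outdir: str | Path) -> dict[str, Path]:
    """Write the evidence TSV, a JSON summary and a plain-text log.

    Row order equals the candidate ranking; p-values use scientific
    notation with 6 significant digits. Output bytes depend only on the
    report content, so reruns on equal inputs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = report.table.copy()
    for col in ("de_p", "de_p_adj"):
        table[col] = table[col].map(_format_float)
    table["de_log2fc"] = table["de_log2fc"].map(
        lambda v: NA_TOKEN if pd.isna(v) else f"{v:.6g}"
    )
    tsv_path = outdir / "evidence.tsv"
    table.to_csv(tsv_path, sep="\t")
    summary = {
        "config": report.config.to_dict(),
        "layer_counts": report.layer_counts,
        "phenotypes": {
            name: {
                "label": call.label,
                "p_value": call.p_value,
                "direction": call.direction,
            }
            for name, call in sorted(report.phenotypes.items())
        },
        "ranked": report.ranked,
        "final_pass": sorted(report.final_pass),
        "side": report.side,
        "provenance": report.provenance,
    }
    json_path = outdir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log_path = outdir / "screen.log"
    log_lines = [
        f"candidates in region: {report.layer_counts['region']}",
        f"passing DE filter: {report.layer_counts['de']}",
        f"passing DE and methylation: {report.layer_counts['de_and_methylation']}",
        f"final pass: {report.layer_counts['final']}",
    ]
    log_path.write_text("\n".join(log_lines) + "\n")
    return {"tsv": tsv_path, "json": json_path, "log": log_path}


def write_study(study, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic study as the full plain-text input bundle + truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    segments = [
        (model.name, iv) for model in study.models for iv in model.dosage_segments
    ]
    paths["models_bed"] = outdir / "models.bed"
    write_bed_segments(segments, paths["models_bed"])
    paths["models_species"] = outdir / "models.species.json"
    paths["models_species"].write_text(
        json.dumps(
            {model.name: model.species for model in study.models},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    paths["annotations"] = outdir / "annotations.tsv"
    write_gene_table(study.annotations, paths["annotations"])

    paths["orthologs"] = outdir / "orthologs.tsv"
    write_ortholog_map(study.synteny, paths["orthologs"])

    pheno_rows = []
    for model, (case, control) in study.phenotype_summaries.items():
        for role, stat in (("case", case), ("control", control)):
            pheno_rows.append(
                {"model": model, "role": role, "mean": stat.mean, "sem": stat.sem, "n": stat.n}
            )
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    pd.DataFrame(pheno_rows).to_csv(paths["phenotypes"], sep="\t", index=False)

    paths["glucose_animals"] = outdir / "glucose_animals.tsv"
    study.glucose_animals.to_csv(paths["glucose_animals"], sep="\t", index=False)

    paths["expression"] = outdir / "expression.tsv"
    study.expression.values.to_csv(paths["expression"], sep="\t")
    paths["samples"] = outdir / "samples.tsv"
    study.sample_sheet.to_csv(paths["samples"], sep="\t")

    paths["methylation_samples"] = outdir / "methylation_samples.tsv"
    study.methylation.group.rename("group").to_frame().rename_axis(
        "sample_id"
    ).to_csv(paths["methylation_samples"], sep="\t")
    paths["beta"] = outdir / "methylation_beta.tsv"
    study.methylation.beta.to_csv(paths["beta"], sep="\t")
    paths["detection_p"] = outdir / "methylation_detection_p.tsv"
    study.methylation.detection_p.to_csv(paths["detection_p"], sep="\t")
    paths["probe_manifest"] = outdir / "probe_manifest.tsv"
    study.methylation.manifest.to_csv(paths["probe_manifest"], sep="\t")
    paths["methylation_expression"] = outdir / "methylation_expression.tsv"
    study.methylation_expression.to_csv(paths["methylation_expression"], sep="\t")
    paths["covariates"] = outdir / "covariates.tsv"
    study.covariates.to_csv(paths["covariates"], sep="\t")

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(
        json.dumps(study.truth, indent=2, sort_keys=True) + "\n"
    )
    return paths
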