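"""Genomic interval algebra and the candidate-region computation.

This module holds the coordinate primitives of the screen: half-open
genomic intervals (BED convention, 0-based start inclusive, end
exclusive), gene annotations, aneuploidy model definitions (sets of
dosage-altered segments at three copies), and the mouse-human ortholog
relation. On top of those it implements the screen's region logic:
genes triplicated in every glycaemia-affected model and in no
non-affected model, projected onto human gene identifiers.

All set operations are exact at base-pair resolution: the result of
``segment_set_op`` covers precisely the positions covered by the
corresponding set operation on the inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, NamedTuple, Sequence

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .phenotype import PhenotypeCall

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "AneuploidyModel",
    "SyntenyMap",
    "IntervalError",
    "ProjectionResult",
    "CandidateRegion",
    "normalize_segments",
    "segment_set_op",
    "genes_in_segments",
    "project_orthologs",
    "candidate_gene_set",
]

SPECIES = ("mouse", "human")
MODEL_SPECIES = ("mouse", "human", "mixed")
STRANDS = ("+", "-", "unknown")
SET_OP_MODES = ("union", "intersect", "subtract")
CONTAINMENT_MODES = ("full", "any_overlap")
DIRECTIONS = ("mouse_to_human", "human_to_mouse")
ORTHOLOG_POLICIES = ("one_to_one_only", "keep_all")


class IntervalError(ValueError):
    """Raised for invalid coordinates or malformed interval requests."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Empty intervals (``start >= end``) are rejected at construction so
    that every represented interval covers at least one base pair.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError("interval chromosome name must be non-empty")
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise IntervalError(
                f"interval coordinates must be integers, got "
                f"{self.chrom}:{self.start!r}-{self.end!r}"
            )
        if self.start < 0:
            raise IntervalError(
                f"interval start must be >= 0, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.start >= self.end:
            raise IntervalError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end} "
                "(start must be < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneRecord:
    """A gene annotation: stable id, display symbol, species and location."""

    gene_id: str
    symbol: str
    species: str
    location: GenomicInterval
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.species not in SPECIES:
            raise ValueError(
                f"gene {self.gene_id}: species must be one of {SPECIES}, got "
                f"{self.species!r}"
            )
        if self.strand not in STRANDS:
            raise ValueError(
                f"gene {self.gene_id}: strand must be one of {STRANDS}, got "
                f"{self.strand!r}"
            )


@dataclass(frozen=True)
class AneuploidyModel:
    """A named aneuploidy model with its dosage-altered (three-copy) segments.

    ``dosage_segments`` are normalized (sorted, merged) at construction so
    they are pairwise non-overlapping. ``species`` describes the coordinate
    system of the segments: ``mouse`` or ``human`` for single-genome models,
    ``mixed`` for models whose segments span both genomes (segment
    chromosome names must then be unambiguous between the two annotation
    sets). A phenotype call may be attached after classification.
    """

    name: str
    species: str
    dosage_segments: tuple[GenomicInterval, ...]
    phenotype: "PhenotypeCall | None" = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("model name must be non-empty")
        if self.species not in MODEL_SPECIES:
            raise ValueError(
                f"model {self.name}: species must be one of {MODEL_SPECIES}, "
                f"got {self.species!r}"
            )
        object.__setattr__(
            self,
            "dosage_segments",
            tuple(normalize_segments(self.dosage_segments)),
        )

    def with_phenotype(self, call: "PhenotypeCall") -> "AneuploidyModel":
        return replace(self, phenotype=call)


class ProjectionResult(NamedTuple):
    """Image of a gene set under the ortholog relation plus unmapped ids."""

    mapped: frozenset
    dropped: frozenset


@dataclass(frozen=True)
class SyntenyMap:
    """Mouse-human ortholog links with an ambiguity policy.

    Under ``one_to_one_only`` (the default for dosage reasoning, where
    many-to-many orthology is ill-defined) every pair in which either
    gene participates in more than one link is removed at construction;
    the removed pairs are kept in ``dropped_ambiguous`` for reporting.
    """

    pairs: tuple[tuple[str, str], ...]
    policy: str = "one_to_one_only"
    dropped_ambiguous: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.policy not in ORTHOLOG_POLICIES:
            raise ValueError(
                f"ortholog policy must be one of {ORTHOLOG_POLICIES}, got "
                f"{self.policy!r}"
            )
        unique = tuple(dict.fromkeys(self.pairs))  # dedupe, keep order
        if self.policy == "one_to_one_only":
            from collections import Counter

            mouse_counts = Counter(m for m, _ in unique)
            human_counts = Counter(h for _, h in unique)
            kept = tuple(
                (m, h)
                for m, h in unique
                if mouse_counts[m] == 1 and human_counts[h] == 1
            )
            dropped = tuple(p for p in unique if p not in set(kept))
            object.__setattr__(self, "pairs", kept)
            object.__setattr__(self, "dropped_ambiguous", dropped)
        else:
            object.__setattr__(self, "pairs", unique)
            object.__setattr__(self, "dropped_ambiguous", ())

    def mouse_to_human(self) -> dict[str, str]:
        return {m: h for m, h in self.pairs}

    def human_to_mouse(self) -> dict[str, str]:
        return {h: m for m, h in self.pairs}


def normalize_segments(
    segments: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Sort intervals by (chrom, start) and merge overlapping or bookended ones.

    The returned list covers exactly the same base pairs as the input and
    contains pairwise disjoint, non-adjacent intervals. Idempotent.
    """
    ordered = sorted(segments, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def _subtract_one(
    a: GenomicInterval, chunks: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Subtract normalized same-chromosome ``chunks`` from a single interval."""
    out: list[GenomicInterval] = []
    cursor = a.start
    for b in chunks:
        if b.end <= a.start or b.start >= a.end:
            continue
        if b.start > cursor:
            out.append(GenomicInterval(a.chrom, cursor, b.start))
        cursor = max(cursor, b.end)
    if cursor < a.end:
        out.append(GenomicInterval(a.chrom, cursor, a.end))
    return out


def segment_set_op(
    a: Iterable[GenomicInterval],
    b: Iterable[GenomicInterval],
    mode: str,
) -> list[GenomicInterval]:
    """Base-pair-exact union / intersection / subtraction of interval sets.

    Inputs need not be normalized; the result always is. ``subtract``
    returns the positions covered by ``a`` but not ``b``.
    """
    if mode not in SET_OP_MODES:
        raise IntervalError(f"unknown set operation {mode!r}; expected one of {SET_OP_MODES}")
    a_norm = normalize_segments(a)
    b_norm = normalize_segments(b)
    if mode == "union":
        return normalize_segments(a_norm + b_norm)
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b_norm:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    if mode == "intersect":
        for iv in a_norm:
            for other in by_chrom_b.get(iv.chrom, ()):
                lo = max(iv.start, other.start)
                hi = min(iv.end, other.end)
                if lo < hi:
                    out.append(GenomicInterval(iv.chrom, lo, hi))
    else:  # subtract
        for iv in a_norm:
            out.extend(_subtract_one(iv, by_chrom_b.get(iv.chrom, ())))
    return normalize_segments(out)


def genes_in_segments(
    genes: Iterable[GeneRecord],
    segments: Iterable[GenomicInterval],
    containment: str = "full",
) -> frozenset:
    """Gene ids whose location lies in (or overlaps) the given segments.

    ``full`` (default): the gene body must lie entirely within a single
    normalized segment -- a partially triplicated gene does not carry a
    functional extra copy. ``any_overlap``: one shared base pair suffices.
    """
    if containment not in CONTAINMENT_MODES:
        raise IntervalError(
            f"unknown containment mode {containment!r}; expected one of "
            f"{CONTAINMENT_MODES}"
        )
    segs = normalize_segments(segments)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in segs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    hits = set()
    for gene in genes:
        loc = gene.location
        for seg in by_chrom.get(loc.chrom, ()):
            if containment == "full" and seg.contains(loc):
                hits.add(gene.gene_id)
                break
            if containment == "any_overlap" and seg.overlaps(loc):
                hits.add(gene.gene_id)
                break
    return frozenset(hits)


def project_orthologs(
    gene_ids: Iterable[str],
    synteny: SyntenyMap,
    direction: str = "mouse_to_human",
) -> ProjectionResult:
    """Map a gene-id set through the ortholog relation.

    Genes with no retained link are not silently lost: they are returned
    in ``dropped``.
    """
    if direction not in DIRECTIONS:
        raise IntervalError(
            f"unknown projection direction {direction!r}; expected one of "
            f"{DIRECTIONS}"
        )
    table = (
        synteny.mouse_to_human()
        if direction == "mouse_to_human"
        else synteny.human_to_mouse()
    )
    ids = set(gene_ids)
    mapped = frozenset(table[g] for g in ids if g in table)
    dropped = frozenset(g for g in ids if g not in table)
    return ProjectionResult(mapped=mapped, dropped=dropped)


class CandidateRegion(NamedTuple):
    """Result of the candidate-gene computation with per-model detail."""

    genes: frozenset
    per_model: dict
    affected: tuple
    unaffected: tuple
    dropped_orthologs: frozenset


def _model_human_gene_set(
    model: AneuploidyModel,
    genes: Sequence[GeneRecord],
    synteny: SyntenyMap,
    containment: str,
) -> tuple[frozenset, frozenset]:
    """Human gene ids dosage-increased in one model, plus unmapped mouse ids.

    Genes are matched against the model's segments irrespective of species
    (chromosome names disambiguate the genomes); mouse hits are projected
    through the ortholog map, human hits contribute directly.
    """
    hit_ids = genes_in_segments(genes, model.dosage_segments, containment)
    species_of = {g.gene_id: g.species for g in genes}
    mouse_hits = {g for g in hit_ids if species_of[g] == "mouse"}
    human_hits = frozenset(g for g in hit_ids if species_of[g] == "human")
    projected = project_orthologs(mouse_hits, synteny, "mouse_to_human")
    return human_hits | projected.mapped, projected.dropped


def candidate_gene_set(
    models: Sequence[AneuploidyModel],
    genes: Sequence[GeneRecord],
    synteny: SyntenyMap,
    affected_label: str = "hyperglycaemic",
    containment: str = "full",
) -> CandidateRegion:
    """Genes dosage-increased in every affected model and in no other model.

    Each model's triplicated gene content is projected to human ids; the
    candidate set is the intersection over models carrying
    ``affected_label`` minus the union over all remaining models
    (any phenotype other than the affected label counts as non-affected,
    so both normoglycaemic and hypoglycaemic lines subtract).
    """
    missing = [m.name for m in models if m.phenotype is None]
    if missing:
        raise ValueError(
            "models without a phenotype call: " + ", ".join(sorted(missing))
        )
    affected = tuple(m for m in models if m.phenotype.label == affected_label)
    unaffected = tuple(m for m in models if m.phenotype.label != affected_label)
    if not affected:
        raise ValueError(
            f"no model carries the affected label {affected_label!r}; "
            "the screen requires at least one affected model"
        )
    per_model: dict[str, frozenset] = {}
    dropped_all: set = set()
    for model in models:
        gene_set, dropped = _model_human_gene_set(model, genes, synteny, containment)
        per_model[model.name] = gene_set
        dropped_all.update(dropped)
    candidate = frozenset.intersection(*(per_model[m.name] for m in affected))
    for m in unaffected:
        candidate -= per_model[m.name]
    return CandidateRegion(
        genes=candidate,
        per_model=per_model,
        affected=tuple(m.name for m in affected),
        unaffected=tuple(m.name for m in unaffected),
        dropped_orthologs=frozenset(dropped_all),
    )
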