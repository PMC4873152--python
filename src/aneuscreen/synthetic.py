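"""Seeded generator of complete synthetic screen studies with planted truth.

The generator emulates the data shapes the screen consumes:

* four aneuploidy mouse/human models with fasting-glucose group summaries
  and per-animal draws (Normal per arm, SD reconstructed from the
  published SEM as ``SD = SEM * sqrt(n)``);
* a syntenic gene annotation -- one mouse chromosome whose genes map
  one-to-one onto a human chromosome -- with model segments arranged so
  that the affected-minus-unaffected region algebra yields a 38-gene
  candidate window containing one planted causal gene;
* a two-group islet expression matrix (77 ND vs 12 T2D by default) with
  log2-Normal noise and a planted disease/control ratio of 1.53 for the
  causal gene, plus an HbA1c covariate linearly linked to causal-gene
  expression;
* a 16-probe methylation panel for the causal gene (34 ND vs 15 T2D
  samples) in which three probes carry a planted negative M-scale
  association with expression calibrated to a target correlation, and
  per-cell Infinium-style detection P-values.

Every draw flows from one :class:`numpy.random.Generator`, so a study is
fully reproducible from its seed, and the returned truth record is
sufficient to recompute every planted effect.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .intervals import AneuploidyModel, GeneRecord, GenomicInterval, SyntenyMap
from .methylation import MethylationMatrix, m_to_beta
from .phenotype import SummaryStat

__all__ = [
    "GlucoseArmSpec",
    "ModelSpec",
    "ExpressionSpec",
    "MethylationProbeSpec",
    "MethylationSpec",
    "SyntheticConfig",
    "SyntheticStudy",
    "published_default_config",
    "generate_study",
    "simulate_association_panel",
    "sample_group_betas",
    "simulate_two_group_expression",
    "slope_for_target_r",
]


@dataclass(frozen=True)
class GlucoseArmSpec:
    """Per-model fasting-glucose sampling parameters (mM)."""

    control_mean: float
    control_sem: float
    control_n: int
    case_mean: float
    case_sem: float
    case_n: int

    def summaries(self) -> tuple[SummaryStat, SummaryStat]:
        case = SummaryStat(self.case_mean, self.case_sem, self.case_n)
        control = SummaryStat(self.control_mean, self.control_sem, self.control_n)
        return case, control


@dataclass(frozen=True)
class ModelSpec:
    """One aneuploidy model: which genes are triplicated, and its glucose arms.

    ``gene_span`` is an inclusive (first, last) pair of 1-based gene
    indices along the synthetic chromosome; the dosage segment is the
    contiguous window that fully contains exactly those gene bodies.
    """

    name: str
    species: str
    gene_span: tuple[int, int]
    glucose: GlucoseArmSpec
    true_label: str


@dataclass(frozen=True)
class ExpressionSpec:
    n_nd: int = 77
    n_t2d: int = 12
    sigma_log2: float = 0.5
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.0
    # disease/control abundance ratios planted per human gene id
    planted_folds: Mapping[str, float] = field(default_factory=dict)
    hba1c_target_r: float = 0.3
    hba1c_nd_mean: float = 5.7
    hba1c_t2d_mean: float = 7.2
    hba1c_sd: float = 0.45


@dataclass(frozen=True)
class MethylationProbeSpec:
    """One CpG probe: optional planted association and group summaries.

    ``target_r`` is the absolute planted methylation-expression
    correlation (the slope is negative). ``nd``/``t2d`` hold published
    group (mean, SEM) pairs on the beta-percent scale where available,
    used for summary-parameterised beta sampling.
    """

    probe_id: str
    planted: bool = False
    target_r: float = 0.5
    baseline_m: float = 0.0
    nd: tuple[float, float] | None = None
    t2d: tuple[float, float] | None = None


@dataclass(frozen=True)
class MethylationSpec:
    n_nd: int = 34
    n_t2d: int = 15
    probes: tuple[MethylationProbeSpec, ...] = ()
    m_noise_sd: float = 1.0
    detection_contamination_rate: float = 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Frozen description of a full synthetic study."""

    seed: int = 0
    n_genes: int = 80
    gene_length: int = 5_000
    gene_spacing: int = 10_000
    mouse_chrom: str = "chr16"
    human_chrom: str = "chr21"
    focal_gene_index: int = 25
    models: tuple[ModelSpec, ...] = ()
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    methylation: MethylationSpec = field(default_factory=MethylationSpec)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (1 <= self.focal_gene_index <= self.n_genes):
            raise ValueError("focal_gene_index outside the synthetic gene range")
        for spec in self.models:
            a, b = spec.gene_span
            if not (1 <= a <= b <= self.n_genes):
                raise ValueError(
                    f"model {spec.name}: gene span {spec.gene_span} outside "
                    f"1..{self.n_genes}"
                )
        for probe in self.methylation.probes:
            if probe.planted and not (0.0 < probe.target_r < 1.0):
                raise ValueError(
                    f"probe {probe.probe_id}: target correlation must be in "
                    f"(0, 1), got {probe.target_r}"
                )
        for gene, fold in self.expression.planted_folds.items():
            if fold <= 0:
                raise ValueError(f"planted fold for {gene} must be > 0, got {fold}")


def mouse_gene_id(i: int) -> str:
    return f"mmu_g{i:03d}"


def human_gene_id(i: int) -> str:
    return f"hsa_g{i:03d}"


# Printed fasting-glucose group summaries (mM) for the four models and the
# per-site methylation summaries (beta percent) for the three correlated
# CpG sites; these are the study conditions the generator reproduces.
GLUCOSE_ARMS = {
    "Ts65Dn": GlucoseArmSpec(8.0, 0.3, 17, 10.9, 0.9, 14),
    "Dp16": GlucoseArmSpec(9.7, 0.5, 10, 12.1, 0.9, 11),
    "Ts1Rhr": GlucoseArmSpec(11.1, 0.6, 18, 11.5, 0.4, 12),
    "Tc1": GlucoseArmSpec(13.6, 0.6, 23, 9.4, 0.5, 23),
}

METHYLATION_SITE_SUMMARIES = {
    "cg05156137-like": ((51.1, 1.8), (40.2, 3.1)),
    "cg21301258-like": ((57.9, 1.9), (48.0, 3.2)),
    "cg05056497-like": ((42.3, 1.5), (29.5, 1.9)),
}

FOCAL_EXPRESSION_RATIO = 1.53  # disease/control percent-of-control 153%


def published_default_config() -> SyntheticConfig:
    """The frozen default study: four models at published glucose summaries,
    a 38-gene candidate window, fold 1.53 for the focal gene, and a
    16-probe focal-gene methylation panel with 3 planted negative sites.

    Model gene spans are an illustrative layout, not a reconstruction of
    the real breakpoints: the two hyperglycaemic models share genes
    15..70, the normoglycaemic model covers 40..47 and the hypoglycaemic
    human-chromosome model 61..70, leaving 38 candidate genes
    (15..39 and 48..60) that include the focal gene at index 25.
    """
    models = (
        ModelSpec("Ts65Dn", "mouse", (15, 78), GLUCOSE_ARMS["Ts65Dn"], "hyperglycaemic"),
        ModelSpec("Dp16", "mouse", (5, 70), GLUCOSE_ARMS["Dp16"], "hyperglycaemic"),
        ModelSpec("Ts1Rhr", "mouse", (40, 47), GLUCOSE_ARMS["Ts1Rhr"], "normoglycaemic"),
        ModelSpec("Tc1", "human", (61, 70), GLUCOSE_ARMS["Tc1"], "hypoglycaemic"),
    )
    focal = human_gene_id(25)
    planted_sites = tuple(METHYLATION_SITE_SUMMARIES)
    probes = tuple(
        MethylationProbeSpec(
            probe_id=name,
            planted=True,
            target_r=0.5,
            baseline_m=float(np.log2(nd[0] / (100.0 - nd[0]))),
            nd=nd,
            t2d=t2d,
        )
        for name, (nd, t2d) in METHYLATION_SITE_SUMMARIES.items()
    ) + tuple(
        MethylationProbeSpec(probe_id=f"cg-synth-{i:02d}") for i in range(1, 14)
    )
    assert len(probes) == 16
    return SyntheticConfig(
        seed=0,
        models=models,
        expression=ExpressionSpec(
            planted_folds={focal: FOCAL_EXPRESSION_RATIO}
        ),
        methylation=MethylationSpec(probes=probes),
    )


@dataclass
class SyntheticStudy:
    """A generated study bundle: every pipeline input plus the planted truth."""

    config: SyntheticConfig
    seed: int
    models: list[AneuploidyModel]
    annotations: list[GeneRecord]
    synteny: SyntenyMap
    phenotype_summaries: dict[str, tuple[SummaryStat, SummaryStat]]
    glucose_animals: pd.DataFrame
    expression: ExpressionMatrix
    sample_sheet: pd.DataFrame
    methylation: MethylationMatrix
    methylation_expression: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict


def _gene_interval(cfg: SyntheticConfig, index: int, chrom: str) -> GenomicInterval:
    start = index * cfg.gene_spacing + 2_000
    return GenomicInterval(chrom, start, start + cfg.gene_length)


def _span_segment(cfg: SyntheticConfig, span: tuple[int, int], chrom: str) -> GenomicInterval:
    first = _gene_interval(cfg, span[0], chrom)
    last = _gene_interval(cfg, span[1], chrom)
    return GenomicInterval(chrom, first.start, last.end)


def slope_for_target_r(target_r: float, expr_sd: float, noise_sd: float) -> float:
    """Planted M-on-expression slope magnitude giving correlation ``target_r``.

    For ``M = -k * expr + noise`` with independent Normal noise,
    ``|r| = k * sd(expr) / sqrt(k^2 sd(expr)^2 + sd(noise)^2)``; solving
    for ``k`` gives ``r / sqrt(1 - r^2) * sd(noise) / sd(expr)``.
    """
    if not (0.0 < target_r < 1.0):
        raise ValueError(f"target correlation must be in (0, 1), got {target_r}")
    return target_r / math.sqrt(1.0 - target_r**2) * noise_sd / expr_sd


def sample_group_betas(
    mean_percent: float, sem_percent: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` beta-values for one group from published (mean, SEM) percent.

    Values are drawn Normal on the percent scale with
    ``SD = SEM * sqrt(n)`` -- so the expected sample mean equals the
    published group mean exactly -- then clipped just inside (0, 100) and
    rescaled to the (0, 1) beta scale.
    """
    sd = sem_percent * math.sqrt(n)
    draws = rng.normal(mean_percent, sd, size=n)
    return np.clip(draws, 1e-3, 100.0 - 1e-3) / 100.0


def simulate_two_group_expression(
    n_nd: int,
    n_t2d: int,
    fold: float,
    sigma_log2: float,
    rng: np.random.Generator,
    baseline_log2: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Abundance draws for one gene: log2-Normal noise, planted group ratio.

    Both groups share ``sigma_log2``, so the ratio of the group
    expectation of abundance equals ``fold`` exactly.
    """
    nd = np.exp2(rng.normal(baseline_log2, sigma_log2, size=n_nd))
    t2d = np.exp2(
        rng.normal(baseline_log2 + math.log2(fold), sigma_log2, size=n_t2d)
    )
    return nd, t2d


def simulate_association_panel(
    n_samples: int,
    probes: Sequence[MethylationProbeSpec],
    rng: np.random.Generator,
    m_noise_sd: float = 1.0,
    expression: np.ndarray | None = None,
    sample_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Generate a per-gene CpG panel with planted negative associations.

    Expression defaults to standard-Normal (log-scale) draws. Planted
    probes receive ``M = m0 - k * (expr - mean(expr)) + Normal(0, sd)``
    with ``k`` calibrated to the probe's target correlation; null probes
    are pure noise around their baseline. Returns the beta frame, the
    expression series and the planted slope per probe id (0 for nulls).
    """
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    if expression is None:
        expression = rng.normal(0.0, 1.0, size=n_samples)
    expression = np.asarray(expression, dtype=float)
    if expression.size != n_samples:
        raise ValueError("expression vector length does not match n_samples")
    expr_sd = float(expression.std(ddof=0))
    if expr_sd == 0:
        raise ValueError("constant expression vector cannot carry an association")
    centered = expression - expression.mean()
    slopes: dict[str, float] = {}
    m_rows = []
    for probe in probes:
        noise = rng.normal(0.0, m_noise_sd, size=n_samples)
        if probe.planted:
            k = slope_for_target_r(probe.target_r, expr_sd, m_noise_sd)
            m_rows.append(probe.baseline_m - k * centered + noise)
            slopes[probe.probe_id] = -k
        else:
            m_rows.append(probe.baseline_m + noise)
            slopes[probe.probe_id] = 0.0
    beta = pd.DataFrame(
        m_to_beta(np.vstack(m_rows)),
        index=[p.probe_id for p in probes],
        columns=list(sample_ids),
    )
    expr_series = pd.Series(expression, index=list(sample_ids), name="expression")
    return beta, expr_series, slopes


def _detection_p(
    shape: tuple[int, int],
    probes: Sequence[str],
    contaminated: Sequence[str],
    rng: np.random.Generator,
) -> np.ndarray:
    """Clean cells ~ U(0, 0.005); contaminated probes ~ U(0.011, 0.2)."""
    out = rng.uniform(0.0, 0.005, size=shape)
    bad = {p for p in contaminated}
    for i, probe in enumerate(probes):
        if probe in bad:
            out[i, :] = rng.uniform(0.011, 0.2, size=shape[1])
    return out


def generate_study(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> SyntheticStudy:
    """Generate a full synthetic study from a config (defaults to the
    published-parameter study) and a seed (defaults to ``config.seed``)."""
    cfg = config if config is not None else published_default_config()
    run_seed = cfg.seed if seed is None else int(seed)
    rng = np.random.default_rng(run_seed)

    # --- genome, annotation, orthology -----------------------------------
    annotations: list[GeneRecord] = []
    pairs = []
    for i in range(1, cfg.n_genes + 1):
        symbol = "Rcan1" if i == cfg.focal_gene_index else f"Gene{i:03d}"
        annotations.append(
            GeneRecord(
                gene_id=mouse_gene_id(i),
                symbol=symbol,
                species="mouse",
                location=_gene_interval(cfg, i, cfg.mouse_chrom),
                strand="+",
            )
        )
        annotations.append(
            GeneRecord(
                gene_id=human_gene_id(i),
                symbol=symbol.upper(),
                species="human",
                location=_gene_interval(cfg, i, cfg.human_chrom),
                strand="+",
            )
        )
        pairs.append((mouse_gene_id(i), human_gene_id(i)))
    synteny = SyntenyMap(pairs=tuple(pairs), policy="one_to_one_only")

    # --- models and glucose ----------------------------------------------
    models: list[AneuploidyModel] = []
    phenotype_summaries: dict[str, tuple[SummaryStat, SummaryStat]] = {}
    animal_rows = []
    for spec in cfg.models:
        chrom = cfg.mouse_chrom if spec.species == "mouse" else cfg.human_chrom
        models.append(
            AneuploidyModel(
                name=spec.name,
                species=spec.species,
                dosage_segments=(_span_segment(cfg, spec.gene_span, chrom),),
            )
        )
        phenotype_summaries[spec.name] = spec.glucose.summaries()
        for role, mean, sem, n in (
            ("control", spec.glucose.control_mean, spec.glucose.control_sem, spec.glucose.control_n),
            ("case", spec.glucose.case_mean, spec.glucose.case_sem, spec.glucose.case_n),
        ):
            sd = sem * math.sqrt(n)
            for k, value in enumerate(rng.normal(mean, sd, size=n), start=1):
                animal_rows.append(
                    {
                        "model": spec.name,
                        "role": role,
                        "animal_id": f"{spec.name}_{role}_{k:02d}",
                        "glucose_mm": float(value),
                    }
                )
    glucose_animals = pd.DataFrame(animal_rows)

    # --- expression cohort -------------------------------------------------
    ex = cfg.expression
    n_samples = ex.n_nd + ex.n_t2d
    sample_ids = [f"ISL{i + 1:03d}" for i in range(n_samples)]
    group = pd.Series(
        ["ND"] * ex.n_nd + ["T2D"] * ex.n_t2d, index=sample_ids, name="group"
    )
    human_ids = [human_gene_id(i) for i in range(1, cfg.n_genes + 1)]
    baselines = rng.normal(ex.baseline_log2_mean, ex.baseline_log2_sd, size=cfg.n_genes)
    log2fold = np.array(
        [math.log2(ex.planted_folds.get(g, 1.0)) for g in human_ids]
    )
    is_t2d = (group == "T2D").to_numpy()
    log2_values = (
        baselines[:, None]
        + np.outer(log2fold, is_t2d.astype(float))
        + rng.normal(0.0, ex.sigma_log2, size=(cfg.n_genes, n_samples))
    )
    expression = ExpressionMatrix(
        values=pd.DataFrame(np.exp2(log2_values), index=human_ids, columns=sample_ids),
        group=group,
    )

    # HbA1c linearly tied to focal-gene log2 expression at the target
    # correlation, on top of a group-level offset; BMI is free noise.
    focal = human_gene_id(cfg.focal_gene_index)
    focal_log2 = log2_values[human_ids.index(focal)]
    z = (focal_log2 - focal_log2.mean()) / focal_log2.std(ddof=0)
    r = ex.hba1c_target_r
    hba1c = (
        np.where(is_t2d, ex.hba1c_t2d_mean, ex.hba1c_nd_mean)
        + ex.hba1c_sd * (r * z + math.sqrt(1.0 - r**2) * rng.normal(size=n_samples))
    )
    sample_sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group.to_numpy(),
            "hba1c": hba1c,
            "bmi": rng.normal(28.0, 4.5, size=n_samples),
        }
    ).set_index("sample_id")

    # --- methylation cohort -------------------------------------------------
    me = cfg.methylation
    m_samples = [f"MET{i + 1:03d}" for i in range(me.n_nd + me.n_t2d)]
    m_group = pd.Series(
        ["ND"] * me.n_nd + ["T2D"] * me.n_t2d, index=m_samples, name="group"
    )
    focal_fold = ex.planted_folds.get(focal, 1.0)
    meth_expr_log2 = (
        ex.baseline_log2_mean
        + np.where(m_group.to_numpy() == "T2D", math.log2(focal_fold), 0.0)
        + rng.normal(0.0, ex.sigma_log2, size=len(m_samples))
    )
    beta, meth_expr, planted_slopes = simulate_association_panel(
        n_samples=len(m_samples),
        probes=me.probes,
        rng=rng,
        m_noise_sd=me.m_noise_sd,
        expression=meth_expr_log2,
        sample_ids=m_samples,
    )
    probe_ids = [p.probe_id for p in me.probes]
    n_contaminated = int(round(me.detection_contamination_rate * len(probe_ids)))
    contaminated = list(
        rng.choice(probe_ids, size=n_contaminated, replace=False)
    ) if n_contaminated else []
    detection_p = pd.DataFrame(
        _detection_p((len(probe_ids), len(m_samples)), probe_ids, contaminated, rng),
        index=probe_ids,
        columns=m_samples,
    )
    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_id": focal,
            "chrom": cfg.human_chrom,
            "position": [
                _gene_interval(cfg, cfg.focal_gene_index, cfg.human_chrom).start + 100 * j
                for j in range(len(probe_ids))
            ],
        }
    ).set_index("probe_id")
    methylation = MethylationMatrix(
        beta=beta, detection_p=detection_p, group=m_group, manifest=manifest
    )
    methylation_expression = pd.DataFrame(
        [meth_expr.to_numpy()], index=[focal], columns=m_samples
    )
    covariates = pd.DataFrame(
        {
            "batch": rng.choice(["b1", "b2"], size=len(m_samples)),
            "gender": rng.choice(["M", "F"], size=len(m_samples)),
            "bmi": rng.normal(28.0, 4.5, size=len(m_samples)),
            "age": rng.normal(60.0, 10.0, size=len(m_samples)),
            "islet_purity": rng.uniform(50.0, 95.0, size=len(m_samples)),
            "days_culture": rng.integers(1, 8, size=len(m_samples)).astype(float),
        },
        index=m_samples,
    )

    # --- truth record (independent integer arithmetic, no interval code) ---
    affected_spans = [s.gene_span for s in cfg.models if s.true_label == "hyperglycaemic"]
    other_spans = [s.gene_span for s in cfg.models if s.true_label != "hyperglycaemic"]
    in_all_affected = set(range(1, cfg.n_genes + 1))
    for a, b in affected_spans:
        in_all_affected &= set(range(a, b + 1))
    for a, b in other_spans:
        in_all_affected -= set(range(a, b + 1))
    truth = {
        "causal_gene": focal,
        "planted_folds": dict(ex.planted_folds),
        "planted_probe_slopes": planted_slopes,
        "planted_probes": sorted(
            p.probe_id for p in me.probes if p.planted
        ),
        "true_phenotypes": {s.name: s.true_label for s in cfg.models},
        "expected_candidates": sorted(human_gene_id(i) for i in in_all_affected),
        "contaminated_probes": sorted(contaminated),
    }

    return SyntheticStudy(
        config=cfg,
        seed=run_seed,
        models=models,
        annotations=annotations,
        synteny=synteny,
        phenotype_summaries=phenotype_summaries,
        glucose_animals=glucose_animals,
        expression=expression,
        sample_sheet=sample_sheet,
        methylation=methylation,
        methylation_expression=methylation_expression,
        covariates=covariates,
        truth=truth,
    )
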