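# Methods

## The screen

The pipeline formalises a comparative dosage screen. Aneuploidy models
(mouse lines trisomic for segments of chromosome 16, or a line carrying
an incomplete human chromosome 21) are classified by fasting blood
glucose into hyper-, normo- and hypoglycaemic. The dosage-sensitive
candidate region is the set of genes triplicated in every
hyperglycaemic model and in none of the others — both normoglycaemic
and hypoglycaemic lines subtract, since their triplicated content
evidently does not produce hyperglycaemia. Candidates are projected to
human orthologs, filtered for upregulation in a disease-vs-control
islet expression cohort, and corroborated by negative
methylation-expression association at the gene's CpG probes. A final
biological-prioritisation step is represented only as an optional
user-supplied per-gene boolean flag; the pipeline never infers it.

## Phenotype layer

Group summaries (mean, SEM, n) are sufficient statistics for the
unpaired t test: SD = SEM·√n, and the reconstructed statistic is
identical to the raw-data test (property-tested to 10 significant
figures). The default variant is the pooled-variance Student test
(df = n₁+n₂−2); Welch-Satterthwaite is exposed because equal variances
cannot be verified from summaries alone. All four shipped model
classifications hold under both variants. The classification α defaults
to 0.05, configurable. A Mann-Whitney rank-sum companion is provided
for raw per-animal tables only — a rank test has no summary
reconstruction. Glucose-tolerance curves are summarized by a
trapezoidal AUC; whether the t = 0 value is subtracted first is a
reporting choice with no stated convention, so both modes exist and the
default is the total (unsubtracted) area.

## Region layer

Coordinates are 0-based half-open everywhere internally (unambiguous
length arithmetic, lossless BED round trips); GFF3 gene rows are
shifted at the reader boundary. Interval normalization merges
overlapping and bookended same-chromosome intervals; union, intersection
and subtraction are exact per base pair and are property-tested against
a brute-force per-position oracle on small genomes. Gene membership
defaults to *full containment* — a partially triplicated gene does not
carry a functional extra copy — with `any_overlap` available. Ortholog
projection defaults to one-to-one links only; pairs with any ambiguity
are dropped and reported, because dosage reasoning is ill-defined for
many-to-many orthology. Models carrying human-chromosome segments
contribute their gene sets directly without projection, so mixed panels
(mouse lines plus a human-chromosome line) work in one pass.

## Expression layer

The screen consumes either precomputed per-gene statistics from an
upstream engine or a normalized gene-by-sample matrix. The in-package
surrogate is an unpaired pooled t test on log2(x+1) values (the
pseudocount bounds the transform at zero expression); a rank-sum option
exists for heavy-tailed data. Fold-change sign is fixed project-wide:
positive means higher in disease. The upregulation filter uses nominal
p < 0.05 over the candidate set by default — matching how a small
candidate panel is typically read — with Benjamini-Hochberg and
Bonferroni options. Genes with zero variance in both groups get p = 1
by convention and are flagged degenerate. Expression-covariate
correlation (e.g. against HbA1c or BMI) defaults to Spearman for
robustness.

## Methylation layer

Probes are excluded when their *mean* detection P across samples
exceeds 0.01 (strict inequality; a probe at exactly the threshold
stays). Statistics run on M-values, M = log2(β/(1−β)), which are
approximately homoscedastic; β remains the reporting scale. β-values of
exactly 0 or 1 are clamped to [1e−6, 1−1e−6] at the reader boundary
with a logged count — the transform itself never clamps. Per-site
association is an OLS of M on focal-gene expression with batch, gender,
BMI, age, islet purity and days-of-culture covariates (categoricals
expanded to indicator contrasts; rank deficiency is an error naming the
collinear columns); with no covariates the fit reduces exactly to
simple linear regression (property-tested). Whether the association is
covariate-adjusted or marginal is a config switch
(`adjust_methylation_covariates`, default on). Sites are flagged when
the slope is negative (methylation falls as expression rises) and the
within-gene Bonferroni-adjusted p falls below α = 0.05; `none` and BH
are available. Group differences are reported as ND-minus-T2D deltas,
in percentage points of β·100 or on the M scale.

## Pipeline semantics

Layers are *required* or *corroborative*. The default requires region
and differential expression, with methylation corroborative, because
methylation evidence is typically examined after selection; the
end-to-end synthetic acceptance run requires all three. A candidate
without methylation probes is marked `no_data`: that fails the
methylation layer only when the layer is required, and is logged either
way. Ranking is total and stable: passing-layer count (desc), DE p
(asc, missing last), flagged-probe count (desc), gene id. Reports are
deterministic: given equal inputs, the evidence TSV and JSON summary
are byte-identical across reruns (fixed column order, 6-significant-
digit scientific notation for p-values, sorted JSON keys, no
timestamps), with provenance limited to seed, version and input
digests.

## Synthetic studies

The generator emulates the data shapes the screen consumes, with every
draw flowing from one seeded `numpy` generator.

* **Genome.** 80 genes on one mouse chromosome, each mapped one-to-one
  to a human ortholog at mirrored coordinates. The default model layout
  is an illustrative fixture, not a reconstruction of real breakpoints
  (which are not published at gene resolution): the two hyperglycaemic
  models share genes 15-70, the normoglycaemic model covers 40-47 and
  the hypoglycaemic human-chromosome model 61-70, leaving a 38-gene
  candidate window containing the focal gene at index 25.
* **Glucose.** Per-animal values are Normal per arm at the published
  group means with SD = SEM·√n and the published group sizes (e.g.
  affected arm 10.9 ± 0.9 mM, n = 14 vs control 8.0 ± 0.3, n = 17).
  The study's phenotype input to the screen is the per-arm summary
  triples at their configured values; this is a deliberate design
  choice. The screen's phenotype layer is a deterministic
  reconstruction from summaries, and the published group sizes are
  small enough that resampling animals re-reaches significance for the
  weakest affected arm (Δ = 2.4 mM at n = 10/11) only ~60% of the time
  — a property of those group sizes, not of the screen. Callers who
  want sampling noise in this layer can pass slices of the generated
  `glucose_animals` table instead; the pipeline accepts raw arrays and
  summarizes them identically.
* **Expression.** log2 abundance is Normal per gene (baseline mean 5,
  SD 1 across genes; residual SD 0.5) over 77 ND and 12 T2D samples;
  the focal gene's T2D mean is shifted by log2(1.53), so the expected
  disease/control abundance ratio is exactly 1.53. HbA1c is a linear
  function of focal-gene log2 expression plus noise tuned to a target
  correlation of 0.3 on top of a group offset — the magnitude is an
  invented default (the reference value is only graphical) and is
  configurable.
* **Methylation.** 16 probes for the focal gene over 34 ND and 15 T2D
  samples. Three probes (named after the three reference CpG sites,
  with a `-like` suffix marking them as synthetic stand-ins) carry a
  planted negative M-scale slope on expression calibrated so the
  planted correlation is −0.5 (slope −r/√(1−r²)·σ_noise/σ_expr, with
  the drawn expression SD used for calibration); the other 13 are
  noise (M-noise SD 1). Because planted slopes live on the M scale,
  generated β stays strictly in (0, 1). Detection P-values are
  U(0, 0.005) for clean cells and U(0.011, 0.2) for contaminated
  probes (contamination rate 0 by default, matching a fully analysable
  panel). For group-summary parameter recovery the generator also
  samples β directly as Normal on the percent scale at the published
  (mean, SEM·√n) per group, so the expected sample mean equals the
  published mean exactly.
* **Covariates.** Batch (2 levels), gender, BMI ~ N(28, 4.5),
  age ~ N(60, 10), islet purity ~ U(50, 95), days of culture ~ U{1..7}
  — plausible ranges with no planted effects.

What passing tests on synthetic data do and do not show: the generator
plants clean Normal effects with independent noise and no batch
structure in the signal, so end-to-end recovery demonstrates the
screen's logic and calibration, not robustness to the correlated noise,
normalization artefacts and confounding of real islet cohorts. The
38-gene window and the single-gene funnel on synthetic data mirror the
reference funnel's shape by construction of the fixture layout.

## Problem sizes and numerical choices

The shipped analyses use the study's own cohort sizes (89 expression
samples, 49 methylation samples, 16 probes, 80 genes) and
100-200 seed replicates for stochastic summaries; property tests use
10,000-replicate nulls where a 2-Monte-Carlo-SE band is asserted.
Tie-breaks in ranking are lexicographic on gene id; degenerate DE genes
get p = 1; the β clamp is 1e−6; detection filtering uses strict
inequality at the threshold. The M-transform printed in compact form as
"log2 β/(1−β)" is implemented as M = log2(β/(1−β)), the standard
Infinium transform (it maps β = 0.5 to 0).

## Known limitations

* No copy-number states other than 3 vs 2; no mosaic fractions.
* Orthology is taken as input; no synteny inference.
* The DE surrogate is not a count model — no dispersion estimation or
  normalization factors; real RNA-seq should arrive as precomputed
  statistics or normalized abundances.
* No Infinium idat parsing or array normalization; scope is per-gene
  probe panels, not genome-wide EWAS.
* The generator does not simulate reads, idat intensities, batch
  effects in the signal, or HbA1c-consistent group assignment (group
  labels and the HbA1c covariate are generated jointly but a sample's
  HbA1c may straddle its group's nominal cutoff).
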