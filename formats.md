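# Input and output formats

All files are plain-text, tab-separated unless noted, parsed
locale-independently (decimal point only; the sole missing-value token
is `NA`). Genomic coordinates are 0-based half-open (BED convention)
except in GFF3, which is converted on read.

## Model dosage segments — BED3+ (`models.bed`)

One three-copy segment per line; column 4 names the model (or a
file-level default is supplied by the caller). `#`, `track` and
`browser` lines are skipped.

```
chr16	152000	787000	Ts65Dn
```

| column | content |
| --- | --- |
| 1 | chromosome name |
| 2 | start, 0-based inclusive, ≥ 0 |
| 3 | end, exclusive, > start |
| 4 | model name (optional with a default) |

An optional sibling file `models.species.json` maps model name to
`mouse`/`human` for the CLI (library callers set species directly).

## Gene annotation — TSV (`annotations.tsv`)

```
gene_id	symbol	species	chrom	start	end	strand
hsa_g025	RCAN1	human	chr21	252000	257000	+
```

`species` ∈ {mouse, human}; `strand` ∈ {+, -, unknown}; `gene_id`
unique. A GFF3 subset reader is also provided: only `gene` features are
used, 1-based inclusive spans become half-open (start − 1), `ID` is the
gene id and `Name` the symbol.

## Ortholog map — 2-column TSV (`orthologs.tsv`)

```
# mouse_gene_id	human_gene_id
mmu_g025	hsa_g025
```

`#` comments allowed. Under the default one-to-one policy, pairs with
any ambiguity are dropped and reported.

## Phenotype table — TSV (`phenotypes.tsv`)

Summary form (one case and one control row per model):

```
model	role	mean	sem	n
Ts65Dn	case	10.9	0.9	14
Ts65Dn	control	8.0	0.3	17
```

Per-animal form: columns `model`, `role` (case/control), `animal_id`,
and `value` (or `glucose_mm`).

## Expression matrix — TSV (`expression.tsv` + `samples.tsv`)

Matrix: first column gene id, header row of sample ids, non-negative
numeric cells. Sample sheet: `sample_id`, `group` (ND/T2D) and optional
continuous covariates (`hba1c`, `bmi`, ...), indexed by sample id.

## Precomputed DE statistics — TSV

Columns `gene_id`, `log2fc` (positive = higher in disease), `p_value`,
optional `p_adj`.

## Methylation bundle — TSV pair + manifest + covariates

* `methylation_beta.tsv` — probe × sample β-values in [0, 1]; cells at
  exactly 0 or 1 are clamped to 1e−6 / 1 − 1e−6 on read (count logged).
* `methylation_detection_p.tsv` — same axes, detection P in [0, 1].
* `probe_manifest.tsv` — `probe_id`, `gene_id`, `chrom`, `position`.
* `methylation_expression.tsv` — gene × methylation-sample expression
  (log/normalized scale) for the genes with probes.
* `covariates.tsv` — per methylation sample: `batch`, `gender`
  (categorical), `bmi`, `age`, `islet_purity`, `days_culture`
  (continuous). The generator's bundle also includes a `group` column
  context via the sample sheet.

## Run configuration — JSON

Two blocks: `screen` (any `ScreenConfig` field; unknown keys rejected)
and `inputs` (paths, relative to the config file). See
`aneuscreen run --help`.

## Outputs

* `evidence.tsv` — one row per in-region candidate, in ranked order:
  `gene_id`, `in_region`, `de_log2fc`, `de_p`, `de_p_adj`, `de_pass`,
  `meth_n_probes`, `meth_flagged`, `meth_status` (tested/no_data),
  `meth_pass`, `annotation_flag`, `layers_passed`, `final_pass`.
  P-values in 6-significant-digit scientific notation.
* `summary.json` — config echo, per-layer counts, phenotype calls,
  ranking, final-pass set, side reports (missing DE genes, dropped
  orthologs, removed probes, flagged probes per gene) and provenance
  (seed, version, input digests). Keys sorted; byte-stable on rerun.
* `screen.log` — per-layer counts in plain text.
* `truth.json` (synthetic bundles) — planted causal gene, folds,
  probe slopes, true phenotypes, expected candidate set.
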