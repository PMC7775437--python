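# File formats

All delimited files are plain UTF-8; floats are written with 17
significant digits so writer/reader pairs round-trip exactly. DNAm
levels are **percent on disk, fraction in memory**.

## Beta CSV (clock substrate)

Comma-separated, one row per sample.

| column      | meaning                                  |
|-------------|------------------------------------------|
| sample_id   | unique sample identifier (index column)  |
| age_weeks   | chronological age, weeks (required)      |
| strain      | strain label (optional)                  |
| `<amp>:<i>` | DNAm percent at CpG *i* of amplicon, 0-based; blank = missing |

Cells outside [0, 100] or non-numeric are read as missing with a
warning.

## Pattern TSV

Tab-separated: `sample_id  amplicon  pattern  count`. Patterns are
strings over `0` (unmethylated), `1` (methylated), `?` (missing call),
one character per CpG in amplicon order; counts are positive integers.

## Model JSON

Schema tag `readclock-model/1`.

* Clock models: `{schema, kind: "multivariable-linear"|"lasso",
  terms: [{cpg, coef}], intercept, meta:{n, seed, lambda, folds, ...}}`.
  Coefficients are weeks per beta-fraction; intercept is weeks.
* Single-read models: `{schema, kind: "single-read", amplicon,
  trajectories: [{cpg, slope, intercept}], epsilon, max_missing_frac}`.
  Slopes are beta-fraction per week.

## Read-age distribution CSV

One row per sample × amplicon (`sample|amplicon` index), columns
`total_reads, age_0 .. age_200`: linear relative read frequencies per
grid age, summing to 1. Log-scaling for heatmaps is applied at
plotting, never stored.

## ddPCR wells CSV

`sample_id, target, n_droplets, pos_meth, pos_unmeth` — one row per
reaction; output adds `lambda_meth, lambda_unmeth, percent_meth,
ci_low, ci_high, saturated`.

## Amplicon panel YAML/JSON

```yaml
amplicons:
  - name: Prima1
    sequence: TACTT...        # uppercase top-strand, unconverted
    cpg_positions: [14, 30]   # 0-based offsets of each CpG's C
    max_mismatch_frac: 0.1    # optional QC overrides
    min_conversion: 0.9
```

## FASTQ

Standard 4-line FASTQ, optionally gzipped (`.gz`); read ids written by
the simulator are `sample:amplicon:index`. Reads are expected anchored
at the amplicon start (amplicon products, no adapter trimming).
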