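# poolscreen

Analysis pipeline for pooled yeast deletion-library fitness screens that
measure *acquired* stress resistance: strains are pretreated with a mild
stress, challenged with a severe dose of H2O2, and outgrown so that
barcode abundance changes report each strain's survival. The package covers
the whole path from raw inputs to biology-level statistics:

- **`synthetic_pool`** — fully synthetic screens with planted ground truth:
  strain catalogs with unique 20-bp up/down tags (pairwise Hamming
  distance ≥ 5), deterministic selection/outgrowth population dynamics over
  a six-sample design (S0–S4A), multiplexed barcode reads (FASTQ), and
  replicated array feature intensities with configurable saturation, noise
  and outliers.
- **`tag_quant`** — mismatch-tolerant demultiplexing (1 mismatch per 6-bp
  index) and tag mapping (2 mismatches per 20-bp tag, non-unique maps
  discarded), full read accounting, outlier-robust feature averaging
  (|x − median| > 5·MAD), quantile normalization, invertible saturation
  correction, and conversion to relative strain abundances.
- **`fitness`** — per-strain log2 abundance changes for every sample
  comparison × replicate × platform (Array/UP/DN), per-column z-scores
  (population sd), platform consensus, and a Table-S5-style TSV format.
- **`strain_calling`** — the four-criterion caller for acquired-resistance
  defects (severe-challenge z ≤ −1; pretreatment-alone z > −1; low-dose
  defect strictly smaller; true in ≥ 2 replicates), correlation-based
  expansion with a criterion-1 guard, the two-dose / multi-library rule for
  single-replicate libraries, an FDR-controlled low-dose sensitivity
  caller (one-sample test + Benjamini–Hochberg), and exclusion rules.
- **`set_analysis`** — Venn region accounting, hypergeometric enrichment
  with Bonferroni control, expression-overlap tests (1.5× rule), and
  hierarchical clustering with uncentered Pearson distance.
- **`network_stats`** — permutation test for genetic/physical interaction
  density within a gene set against 1000 random same-size sets.
- **`validation_stats`** — dose-summed survival scores and GFP-competition
  fitness defects.
- **`pipeline` / `reproduce`** — end-to-end orchestration on synthetic
  inputs, and recomputation of headline screen counts from a deposited-style
  fitness table.

## CLI

A full synthetic screen, end to end:

```sh
cat > screen.yaml <<EOF
catalog: {homozygous: 100}
pretreatments: [NaCl]
replicates: 2
depth: 50000
error_rate: 0.005
planted: {n_acquired: 10, acquired_survival: 0.2}
EOF

poolscreen simulate --config screen.yaml --seed 7 --outdir run/
poolscreen quantify reads --catalog run/catalog.tsv \
    --samplesheet run/samplesheet.tsv --fastq-dir run/ --outdir run/
poolscreen fitness --abundances run/abundance.tsv \
    --comparisons run/comparisons.tsv --out run/fitness.tsv --floor 1e-5
poolscreen call --fitness run/fitness.tsv --pretreatment NaCl \
    --catalog run/catalog.tsv --out run/calls.tsv
```

Further subcommands: `quantify array`, `lowdose`, `overlap`, `enrich`,
`cluster`, `network`, `validate survival|competition`. Every command
supports `--help`.

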