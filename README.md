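# woundarray

Analysis pipeline for four-condition wound-response microarray designs:
two sorted cell populations (JNK-positive and JNK-negative) profiled in
wounded and non-wounded imaginal discs, three replicates each. The package
covers the full path from raw intensities to biological summaries, driven
by a synthetic-data generator with planted, known structure.

Stages:

1. **synthetic** — expression matrices with planted per-condition log2
   effects (realizing wounded-only and shared-response sign patterns),
   planted chromosomal runs of co-directional genes, planted discrete
   level profiles, and a small DAG ontology with a designated enriched
   term; everything seeded and bit-reproducible.
2. **preprocess** — non-specific intensity/IQR filtering (>40 units in
   ≥25% of samples; row IQR above the 10th percentile of row IQRs), log2
   transform, between-array quantile normalization, and optional
   median-polish probe-set summarization.
3. **differential** — per-gene cell-means linear model, empirical-Bayes
   moderated t (method-of-moments prior on log variances), log-odds of
   differential expression, Benjamini–Hochberg FDR, and FC/p threshold
   selection for the W (wounded), NW (non-wounded) and D (interaction)
   contrasts.
4. **set_logic** — Venn membership over W/NW/D (7 regions), the WO
   (wounded-only) and W/NW/D composite sets, and sign-pattern subset
   classification (4 simple WO subsets; 6 autonomous + 6 non-autonomous
   W/NW/D subsets; systematic complex codes).
5. **templates** — discretization of 4-condition profiles into 3 levels,
   enumeration of the 81 level templates, and Pearson R² > 0.95 template
   matching.
6. **positional** — gene-coordinate assignment (BED6 / refGene-style TSV),
   per-arm hypergeometric enrichment with a randomization cross-check, and
   sliding-window detection of co-directional gene clusters with a
   stratified permutation null.
7. **go_enrichment** — OBO 1.2 parsing, level-3 projection of annotations
   (minimum is_a path, root = level 1), and per-term hypergeometric
   over-representation.

## CLI

```sh
woundarray simulate  --seed 1 --outdir out           # synthetic dataset + truth
woundarray run-all   --seed 1 --outdir out           # full pipeline
woundarray de        --fc 1.3 --alpha 0.05 --adjusted
woundarray sets      --fc 1.3 --alpha 0.05
woundarray templates --r2 0.95 --flat-eps 0.5
woundarray clusters  --min-de 3 --window 10 --nrand 100
woundarray go        --namespace molecular_function --alpha 0.05
```

All subcommands accept `--config cfg.yaml` (see
`woundarray.config.PipelineConfig` for the schema), `--seed`, `--outdir`
and `--log-level`. Every run writes stage TSVs plus `manifest.json`
recording parameters, the seed, and per-stage counts; re-running with the
same seed reproduces the manifest exactly.

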