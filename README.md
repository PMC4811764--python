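# sarcosig

Gene-signature analysis toolkit for sarcoma expression cohorts:

- **Signature scoring** — per-sample signed-sum scores (expression added for
  up genes, subtracted for down genes), optionally on per-gene standardized
  values; z-scores against a normal-tissue panel; pooled or Welch t-tests of
  score differences between groups.
- **Stratification** — top-fraction (e.g. top 25%) sample selection,
  one-sided hypergeometric subtype enrichment, overlap (Venn) testing of two
  sample sets, and hierarchical clustering of samples on signature genes with
  per-cluster subtype enrichment.
- **Signature construction** — cross-species homolog translation, overlap of
  two directional signatures (discordant genes dropped and reported),
  differential-expression signatures (two-sample t + Benjamini–Hochberg),
  and platform restriction with coverage reporting.
- **Auxiliary quantification** — qPCR standard-curve relative copy number of
  a target locus versus a control locus and a non-amplified reference sample;
  FISH per-cell summaries (target/centromere ratio, % cells with >4 target
  signals, mean target signals per cell); screen positivity percentages.
- **Synthetic data** — simulated expression cohorts with planted additive
  signature shifts and full ground truth, simulated qPCR plates (dilution
  series + samples with planted copy numbers) and FISH cell tables, so every
  stage is testable without external data.

## File formats

All formats are plain tab-separated text:

- expression matrix: rows = genes, first column `gene_id`, header = sample IDs
- sample metadata: `sample_id`, `subtype`
- signatures: GMT with two records per signature, `NAME_UP` and `NAME_DN`
- homolog map: two columns (`source_id`, `target_id`), one row per pair
- qPCR Ct table (long format): `well`, `sample_id`, `assay`,
  `role` (standard|sample), `log10_quantity` (blank for samples), `ct`
- FISH cells: `cell_id`, `met_count`, `cen7_count`

## CLI

The `sarcosig` entry point groups one subcommand per stage:

```sh
# simulate a cohort / qPCR plate / FISH table from a YAML config
sarcosig simulate cohort --config cohort.yaml --seed 1 --out out/
sarcosig simulate qpcr   --config qpcr.yaml   --seed 1 --out out/
sarcosig simulate fish   --config fish.yaml   --seed 1 --out out/

# build signatures
sarcosig build-signature overlap --a fukada.gmt --b pallafacchina.gmt \
    --homolog-map mouse2human.tsv --policy expand --out satellite.gmt
sarcosig build-signature de --matrix x.tsv --metadata samples.tsv \
    --group-a FIBRO --group-b CARDIO --alpha 0.05 --out fibroblast.gmt
sarcosig build-signature restrict --signature met.gmt --platform genes.txt \
    --out met_u133a.gmt

# score, compare, stratify, cluster
sarcosig score --matrix x.tsv --signature met.gmt --out scores.tsv
sarcosig compare --scores scores.tsv --metadata samples.tsv \
    --group-a ERMS --group-b ARMSp --tails 1 --variance heteroscedastic
sarcosig enrich top --scores scores.tsv --metadata samples.tsv \
    --fraction 0.25 --label ERMS
sarcosig enrich venn --a high_met.txt --b high_satellite.txt --universe all.txt
sarcosig cluster --matrix x.tsv --signature met.gmt --metadata samples.tsv \
    --k 5 --linkage complete --distance euclidean --out clusters/

# copy number and FISH
sarcosig cnv --ct ct.tsv --target Met --control Actl6a --reference REF
sarcosig fish --cells fish_cells.tsv
```

## Conventions

- Scores use raw normalized log expression by default; per-gene
  standardization is opt-in (`--standardize`).
- Top-fraction size is `ceil(fraction * n)` (floor selectable); ranking ties
  are broken by sample ID for reproducibility.
- Enrichment is one-sided over-representation; p-values are raw by default.
- Clustering default is Euclidean distance + complete linkage on per-gene
  standardized rows; both are flags.
- qPCR technical replicates are collapsed by mean Ct before the quantity
  transformation; FISH ratio is ratio-of-means (mean-of-ratios via flag).
- Simulators derive all randomness from a single seed via deterministic
  sub-streams: same config + seed ⇒ byte-identical output files.
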