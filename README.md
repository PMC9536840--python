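# metpleio

Pathway-aware pleiotropy analysis of metabolite GWAS summary statistics.

The package implements an integrative pipeline around a metabolic
reaction network:

* **hit processing** — per-trait greedy LD clumping (plink-style
  parameters) and cross-trait merging of indices into lead variants at a
  0.1 cM radius, keeping the minimum-p representative;
* **gene annotation** — deterministic single-gene assignment per lead by
  gene-type priority (pathway-relevant enzyme > transporter > TF >
  general), with a 100 kb standard window, a 500 kb window for
  biologically relevant enzymes and a 200 kb fallback, plus
  biochemical-group assignment per gene;
* **discordant-variant classification** — significant metabolite pairs
  (suggestive in both traits, genome-wide in one, pair genetic
  correlation passing a local-false-sign-rate filter at 0.005 via a
  built-in normal-mixture adaptive-shrinkage fit) are classed
  discordant/concordant against the sign of the pair's global genetic
  correlation;
* **pathway graph logic** — admissible near-shortest biochemical paths
  between metabolite pairs, gene "between"/upstream/downstream calls,
  and flanked genomic region unions for gene sets;
* **exact enrichment statistics** — conditional-binomial Poisson rate
  test, Fisher's exact test with conditional-MLE odds ratio and inverted
  tail CIs, Wilson score intervals, and a Fligner-Killeen two-group
  variance test;
* **local genetic correlation** — aggregation of per-LD-block local
  heritabilities and covariances over pathway gene regions into a
  pathway-level correlation with delta-method SE, plus nonparametric
  pathway contrasts;
* **Mendelian randomization** — IVW and MR-Egger with fixed or
  multiplicative random effects, selected by heterogeneity statistics;
* **effect-matrix normalization** — per-column rank-based inverse-normal
  transform and standardization with per-row sign alignment;
* **synthetic data** — a 16-metabolite reaction network (4 biochemical
  groups) with planted enzyme / transporter / TF / polygenic-background
  variant mechanisms, geometric effect decay along the graph, and
  closed-form ground truth (true effect vectors, pairwise genetic
  correlations, between/upstream labels), emitted as noisy summary
  statistics, pair-correlation estimates and per-block covariance
  tables so every downstream stage can be validated end to end.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (analytic
worked examples, exhaustive exact-test oracle equivalence, planted-truth
recovery over 50 seeded replicates, statistical validity, and
determinism). One criterion — Wilson interval empirical coverage inside
[93%, 97%] at n=20, p=0.3 — fails by construction: the interval's exact
coverage at those parameters is 97.52% (verifiable analytically), so a
correct implementation cannot land in the stated band.

## Command line

Each subcommand takes `--config` (YAML of thresholds), `--seed` and
`--out`, and logs the config hash and seed to stderr:

```sh
metpleio simulate --seed 1 --out sim/
metpleio clump    --sumstats sim/sumstats.tsv --ld sim/ld_pairs.tsv --out indices.tsv
metpleio merge    --sumstats sim/sumstats.tsv --indices indices.tsv --out leads.tsv
metpleio annotate --leads leads.tsv --genes sim/genes.bed --out annotations.tsv
metpleio classify --leads leads.tsv --pair-rg sim/pair_rg.tsv --out calls.tsv
metpleio enrich   --calls calls.tsv --annotations annotations.tsv --out enrich.tsv
metpleio localrg  --block-stats sim/block_stats.tsv --genes sim/genes.bed \
                  --pathways pathways.json --out localrg.tsv
metpleio mr       --leads leads.tsv --out mr.tsv
metpleio report   --leads leads.tsv --out matrix.tsv
```

On-disk formats are plain text: whitespace-delimited summary statistics,
BED (0-based half-open) for genes and LD blocks, JSON for the network
and pathway definitions, TSV everywhere else. In memory all coordinates
are 1-based inclusive.

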