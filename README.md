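# metabotyper

Analysis pipeline linking an ex vivo drug-turnover phenotype ("metabotype")
of gut microbial communities to metagenome features. Given per-replicate
LC-MS/MS peak areas of a glucuronidated substrate, its deconjugated product
and an internal standard, the package

1. fits internal-standard-normalized calibration curves (OLS with ICH-style
   LLOD/LLOQ) and back-calculates concentrations (`metabotyper.quant`),
2. computes percent product formation per individual and splits the cohort
   into low/high metabotypes at the largest gap (`metabotyper.quant`),
3. finds features (taxa, gene families, transporters, orthologous groups)
   differentially abundant between metabotypes with Welch's two-sided
   t-test, Storey FDR q-values (q < 0.05) and a ratio-of-proportions
   effect-size filter (≥ 2), plus a Shapiro–Wilk QC gate
   (`metabotyper.differential`),
4. contrasts the evenness of a gene's vs a taxon's distribution across
   samples with Simpson's equitability (`metabotyper.diversity`), and
5. classifies enzymes by metabotype odds ratio (Haldane-corrected,
   enriched/associated/other/depleted), builds the directed
   product→substrate enzyme network, bins enzymes into betweenness
   centrality tertiles, and tests whether metabotype-associated enzymes
   are peripheral (Wilcoxon rank-sum, per-tier hypergeometric tests,
   Spearman score/topology correlation) (`metabotyper.network`).

`metabotyper.synthetic` generates every input table (time courses,
calibration tables, log-normal feature matrices with planted fold changes,
chain-structured reaction annotations with known peripheral enzymes) from
explicit seeds, with a JSON truth sidecar, so the whole pipeline runs and
is tested without any external data.

## Command line

All stages are exposed under one entry point (exit codes: 0 ok,
1 validation error, 2 runtime error):

```sh
# generate inputs (turnover | features | reactions | calibration)
metabotyper simulate turnover --config cohort.json --seed 7 --out data/

# quantify + percent formation, then classify metabotypes
metabotyper quant --timecourse data/timecourse.tsv \
    --calibration data/calibration.tsv --substrate-initial 100 --out out/
metabotyper classify --quant out/percent_formation.tsv --min-gap 10

# differential abundance, evenness, enrichment/network
metabotyper diffab --features data/features_BG.tsv --labels out/metabotype.tsv \
    --q 0.05 --effect 2.0
metabotyper evenness --features data/features_BG.tsv --entity BG000
metabotyper enrich --features data/features_KO.tsv --labels out/metabotype.tsv \
    --reactions data/reactions.tsv --out out/

# everything in one reproducible run
metabotyper run --config run.json
metabotyper validate --config run.json
```

A `run.json` drives the full pipeline; `"simulate"` and `"inputs"` are
mutually exclusive:

```json
{
  "out_dir": "runs/demo",
  "seed": 1,
  "simulate": {
    "cohort": {},
    "features": {
      "KO": {"baseline_log_sd": 0.25, "planted": "peripheral"},
      "BG": {"n_features": 150, "baseline_log_sd": 0.25, "planted": [[0, 4.0]]},
      "taxon": {"n_features": 12, "baseline_log_sd": 1.0}
    },
    "reactions": {"n_chains": 10, "chain_length": 6, "cross_links": 12}
  },
  "thresholds": {"q": 0.05, "effect": 2.0, "min_gap": 10.0, "lambda": 0.5, "p": 0.05}
}
```

The run writes per-stage TSVs (quant, metabotype assignment, differential
results per category, evenness, enrichment classification, edge list,
centrality tiers), a GraphML export, `network_stats.json` and a
deterministic `report.json` (same config + seed ⇒ byte-identical report).

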