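# rxbench

Consensus drug-repurposing prediction from compound–protein interaction
signatures, with a full benchmarking harness: leave-one-out recall metrics,
NDCG, null controls, parameter optimization, and per-indication feature
analysis. Everything runs on plain-text inputs and ships with a synthetic
data generator, so the whole pipeline is testable end to end without any
downloads.

## What it does

1. **Interaction scoring** (`rxbench.sites`) — builds a compound × protein
   score matrix from per-compound fingerprints and a binding-site library
   (protein id, site id, predicted-ligand fingerprint, site confidence).
   Three scoring types: `C` (best ligand Tanimoto only), `CxP` (× site
   score), `dCxP` (per-protein percentile of the chemical score × site
   score).
2. **Similarity lists** (`rxbench.signatures`) — signature distance is the
   RMSD between score vectors; every compound gets a ranked list of all
   other compounds, ties broken by compound id.
3. **Consensus prediction** (`rxbench.consensus`) — for an indication's
   associated drugs, candidates are ordered by how many of those drugs'
   lists contain them within a similarity-list cutoff, then by mean rank
   within the cutoff, mean full-list rank, mean distance, and id.
4. **Benchmarking** (`rxbench.benchmark`) — the original similarity-list
   protocol (IA/AIA) and the leave-one-out consensus protocol: withhold each
   associated drug, rank it with the remaining drugs as seeds, and report
   nIA/nAIA (percent recovered within rank cutoffs 10/25/100) and nNDCG
   (DCG = 1/log2(rank+1), ideal = 1). Null controls: analytic `100·k/N`
   nAIA and column-permuted-matrix nNDCG.
5. **Optimization** (`rxbench.optimize`) — seeded 30/70 indication-grouped
   split, similarity-list-cutoff sweeps, optimum selection, and a
   three-way scoring-type comparison.
6. **Feature analysis** (`rxbench.features`) — Spearman correlation of
   per-indication nIA with indication size, IA, and three intra-indication
   chemical-similarity summaries; head-to-head comparison of two mappings
   over matched indications and shared associations.
7. **Synthetic data** (`rxbench.synthetic`) — planted-cluster matrices,
   mappings, fingerprints, and site libraries with tunable noise, for
   testing and calibration.

## CLI

All commands operate on TSV/JSON files; stochastic steps take `--seed`.

```bash
# end-to-end demo on synthetic data
rxbench simulate --n-compounds 50 --n-indications 5 --noise-sd 0.05 \
    --seed 0 --out-dir demo
rxbench score --fingerprints demo/fingerprints.tsv --sites demo/sites.tsv \
    --scoring-type CxP --out demo/scored.tsv
rxbench similarity --matrix demo/matrix.tsv --top 10 --out demo/lists.tsv
rxbench predict --matrix demo/matrix.tsv --mapping demo/mapping.tsv \
    --indication ind000 --cutoff 10 --out demo/predictions.tsv
rxbench benchmark --matrix demo/matrix.tsv --mapping demo/mapping.tsv \
    --cutoff 10 --controls --seed 0 --out-dir demo/bench
rxbench optimize --matrix demo/matrix.tsv --mapping demo/mapping.tsv \
    --cutoffs 1:30 --seed 0 --out-dir demo/opt
rxbench analyze --matrix demo/matrix.tsv --mapping demo/mapping.tsv \
    --fingerprints demo/fingerprints.tsv --cutoff 10 --out-dir demo/feat
rxbench compare --assoc-a a/associations.tsv --assoc-b b/associations.tsv \
    --indications-a a/indications.tsv --indications-b b/indications.tsv \
    --match match.tsv --out cmp.json
```

File formats (all TSV with header rows): interaction matrix (first column
compound ids, remaining columns protein ids); mapping (`drug_id`,
`indication_id`, extra columns ignored); fingerprints (`compound_id`,
`bit_space`, comma-separated set bits); site library (`protein_id`,
`site_id`, `site_score`, `bit_space`, `ligand_bits`); 2-column indication
match table. Benchmark output: `indications.tsv`, `associations.tsv`
(per-withheld-drug ranks), `summary.json`.

## Reproducibility notes

- Every stochastic operation (synthetic generation, mapping splits,
  randomized controls) takes an explicit seed and is bit-reproducible.
- Consensus ordering is a deterministic total order: count desc, mean
  cutoff rank asc, mean full-list rank asc, mean distance asc, id asc.
- All ranks are 1-based, in memory and in files.
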