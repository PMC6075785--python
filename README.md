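# fusewalk

Domain-based network inference for gene fusions: given which protein
domains a fusion retains from its two parental genes, fusewalk

1. predicts the protein–protein and protein–DNA interaction partners the
   chimeric protein inherits (domain–domain interaction support for PPI
   neighbors; retained DNA-binding domains for regulatory targets),
2. scores every gene in a compiled gene network for functional
   association with the fusion by random walk with restart from those
   partners,
3. identifies associated pathways by running-sum (GSEA-style) enrichment
   over the association ranking,
4. integrates two-group expression data: a differential-expression
   ranking feeds a parallel deregulation enrichment, and per-pathway
   association/deregulation p-values are combined with the truncated
   product method (only p-values ≤ τ enter the product; closed-form null
   tail for two p-values),
5. maps drug–target tables onto the top-ranked genes, prioritizes
   synergistic targets by fold-change/p filters, and evaluates rankings
   by ROC/AUC against benchmark gene sets.

A deterministic synthetic-data generator (`fusewalk.synthetic`) builds
complete toy input bundles with a planted network module, planted
pathway, and planted expression shift, so the whole pipeline is testable
offline.

## CLI

Each stage is a subcommand; every run writes its outputs plus a
`manifest.json` provenance record (input digests, config snapshot,
version) into `--out-dir`. All inputs and outputs are plain TSV / GMT /
JSON.

```bash
fusewalk simulate --out-dir data --seed 3                 # synthetic bundle
fusewalk predict-partners --out-dir partners \
    --fusion data/fusion.txt --domains data/domains.tsv \
    --ppi data/ppi.tsv --ddi data/ddi.tsv \
    --tf data/tf_targets.tsv --dna-binding data/dna_binding.txt
fusewalk propagate --out-dir prop --network data/network.tsv \
    --partners partners/partners.tsv --gamma 0.7
fusewalk associate --out-dir assoc --scores prop/scores.tsv \
    --gmt data/pathways.gmt --n-perm 1000 --seed 1
fusewalk deregulate --out-dir dereg --expression data/expression.tsv \
    --labels data/labels.tsv --case-group case --gmt data/pathways.gmt --seed 2
fusewalk combine --out-dir comb --assoc assoc/association.tsv \
    --dereg dereg/deregulation.tsv --tau 0.01
fusewalk map-drugs --out-dir drugs --scores prop/scores.tsv \
    --drug-targets data/drug_targets.tsv --fraction 0.10
fusewalk evaluate --out-dir eval --scores prop/scores.tsv \
    --benchmark data/benchmark.txt --exclude PARENT5,PARENT3
```

`--config FILE` points at a `key = value` file supplying defaults that
explicit flags override.

## Key conventions

- Restart probability γ defaults to 0.7; the convergence tolerance is the
  L1 change between iterates (default 1e-30, capped at `--max-iter` with
  a warning since float64 cannot always reach it).
- Dangling (degree-0) nodes get restart-only handling: their probability
  mass returns to the seed distribution, preserving Σp = 1.
- Enrichment p-values use a gene-set permutation null with the
  same-sign-normalized convention, so null p-values are uniform on (0,1).
- Truncated product: W = 1 (no p-value ≤ τ) maps to combined p = 1; the
  two p-values are treated as independent, which shared pathway
  membership violates — the combined p is a ranking statistic, not a
  calibrated error rate.
- Top-fraction selection uses the ceiling convention
  (⌈fraction·N⌉ genes).

## Layout

- `src/fusewalk/fusion_model.py` — domain annotations, fusion specs
- `src/fusewalk/interaction_inference.py` — inherited-partner prediction
- `src/fusewalk/propagation.py` — transition matrix, restart walk, dense-solve oracle
- `src/fusewalk/enrichment.py` — ranking, running-sum ES, permutation p-values
- `src/fusewalk/integration.py` — differential ranking, truncated product combination
- `src/fusewalk/targets_eval.py` — top-fraction selection, drug mapping, ROC/AUC
- `src/fusewalk/io_formats.py` — TSV/GMT/expression readers and writers, manifests
- `src/fusewalk/synthetic.py` — planted-module scenario generator, worked example
- `src/fusewalk/cli.py` — subcommand wiring
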