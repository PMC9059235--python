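# amprep

Replicate-level evaluation of DNA-extraction protocols for milk microbiome
amplicon data. Starting from an ASV count table, a taxonomy table and
replicate-design metadata, the package provides:

* **Curation** (`amprep.curation`) — blank-control-based rules: removal of
  ASVs present only in water extraction controls, removal of single hits,
  a 500-read sample depth filter, a 0.01% pooled relative-abundance taxon
  filter, flagging (without removal) of ASVs recurring across blanks
  (> 2 replicates with at least one count > 100), flagging of taxa
  implausible for milk (index-swap candidates) with the per-run percentage
  of milk reads they carry, and TSS normalization. `run_curation` chains the
  rules in fixed order and emits a per-ASV/per-sample disposition ledger.
* **Alpha diversity** (`amprep.diversity`) — protocol-specific rarefaction
  (subsampling without replacement; min-retained-per-protocol policy or
  explicit depths), Shannon (nats), richness, Pielou evenness, an analytic
  hypergeometric expected-richness oracle, and one-way ANOVA across
  prototype samples.
* **Reproducibility** (`amprep.reproducibility`) — Bray–Curtis distance
  matrices, classical-scaling PCoA, mean within-group dissimilarity,
  a sequencing-vs-total clean-read variability decomposition (largest
  within-extract range vs. largest between-extract difference; ratios above
  100% are meaningful), and the median-clean-reads > 1000 protocol-selection
  rule.
* **Synthetic studies** (`amprep.simulate`) — a generator reproducing the
  nested design (4 prototype milk samples in a 2×2 SCC/cfu layout, six
  protocols with duplicate/triplicate extractions plus per-extract water
  controls, optional triplicate re-sequencing, MOCK/NTC controls, two primer
  runs) with kit-specific blank contaminants, index-swapped reads from a
  labeled foreign pool, and a full planted-truth ledger. Deterministic under
  a single top-level seed via named substreams.
* **Pipeline & CLI** (`amprep.report`, `amprep.cli`) — a YAML-configured
  end-to-end run writing every intermediate as TSV plus a run log.

All I/O is plain-text TSV (abundance, taxonomy, metadata); no binary formats.

## CLI

```sh
amprep simulate --phase main --seed 7 --out sim/
amprep curate --table sim/simulated_counts.tsv --metadata sim/metadata.tsv \
              --taxonomy sim/taxonomy.tsv --out curated/
amprep select --table sim/simulated_counts.tsv --metadata sim/metadata.tsv
amprep variability --table sim/simulated_counts.tsv --metadata sim/metadata.tsv --out var.tsv
amprep diversity --table curated/curated_counts.tsv --metadata sim/metadata.tsv --out div.tsv
amprep betadiv --table curated/curated_counts.tsv --metadata sim/metadata.tsv \
               --run V1V2 --out beta/
amprep all --config run.yaml          # full pipeline from a YAML config
```

Minimal `run.yaml`:

```yaml
seed: 9
outdir: out
simulate:
  phase: main
curation:
  foreign_taxa: [Aquabacterium, Pelomonas, Acidocella]
```

Replace the `simulate:` block with
`inputs: {table: ..., metadata: ..., taxonomy: ...}` to analyse real tables.

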