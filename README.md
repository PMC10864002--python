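# ifnsig

Analysis toolkit for an interferon-stimulated neutrophil gene-signature
workflow: cross-species functional-signature construction and scoring,
bulk RNA-seq deconvolution with per-group profile imputation, a
negative-binomial model-based bootstrap for signature-enrichment statistics,
and biomarker evaluation by rank tests and stratified-bootstrap ROC.
A built-in synthetic-data generator with planted ground truth makes every
stage testable offline.

## Modules

| Module | Purpose |
| --- | --- |
| `ifnsig.core_io` | Validated containers (`ExpressionMatrix`, `GeneSet`, `SampleMetadata`); CSV/MTX/GMT readers and writers; CPM/log-CPM normalization; cell filtering |
| `ifnsig.synthetic` | Single-cell, bulk-cohort and flow-table simulators returning a `SyntheticTruth` record |
| `ifnsig.scoring` | Per-cell binned-control module scores; per-sample rank-ECDF random-walk enrichment (GSVA-style); per-dataset score normalization |
| `ifnsig.markers` | Functional-signature union, enriched-cluster detection, rank-test marker derivation, exclusivity filtering |
| `ifnsig.deconv` | NNLS cell-type fraction estimation against a reference signature matrix; per-group cell-type profile imputation (mean + CV) |
| `ifnsig.nbboot` | NB dispersion `alpha = CV^2 - 1/mu` (Poisson-floored), replicate simulation, scoring and NR-vs-R comparison, multi-dataset panels |
| `ifnsig.biomarkers` | Mann-Whitney tests (exact for small tie-free samples), AUC, stratified-bootstrap percentile CIs, biomarker comparison tables |
| `ifnsig.cli` / `ifnsig.pipeline` / `ifnsig.config` | Subcommand CLI, YAML config with overrides, end-to-end pipelines and run manifests |

Packaged fixtures (`ifnsig/data/`): the 15-gene neutrophil IFN signature
(`neut_ifn15.gmt`), the 6-gene IFN-gamma comparator (`ifng6.gmt`), three
pathway-style gene sets (`functional_sets.gmt`) and a 10-cell-type reference
profile matrix (`lm10_like.csv`).

## CLI

```bash
ifnsig simulate --kind bulk --seed 1 --out-dir sim        # synthetic data
ifnsig score --matrix m.csv --gmt sets.gmt --method gsva  # per-sample scores
ifnsig deconvolve --bulk bulk.csv --meta meta.csv         # fractions + profiles
ifnsig bootstrap --profiles profiles.csv --nreps 50       # NB bootstrap panel
ifnsig evaluate --table flow.csv --biomarkers ly6e_hi_freq
ifnsig pipeline sc --seed 7 --out-dir out_sc              # signature derivation
ifnsig pipeline bulk --seed 7 --out-dir out_bulk          # full bulk panel
```

Each pipeline writes a `manifest.json` (config + derived stage seeds +
version) sufficient to reproduce the run; all randomness flows from the
single root seed.

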