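# phosphoflow

Comparative tyrosine-phosphoproteomics analysis pipeline with an aCGH
copy-number arm and a ground-truth synthetic data generator.

Given MaxQuant-"Evidence"-style pY peptide tables, spike-in standard
declarations, gene sets (GMT), interaction edge lists and aCGH probe tables,
the pipeline performs:

- **preprocess** — contaminant/reverse and localization-probability (≥0.75)
  filtering, spike-in normalisation (per-sample geometric-mean factors),
  log10 site × sample matrix assembly, 75%-presence filtering per class, and
  conditional imputation (k-NN for sites observed in >50% of samples,
  row-min / column-mean fallback otherwise, with per-cell provenance tags);
- **diffstats** — empirical-Bayes moderated t contrasts between tumour
  classes, Storey-type tail-area q-values, and class-specific site calling
  (significant vs both other classes with the highest class mean, behind an
  optional moderated-F omnibus screen);
- **signature** — a two-step random forest: per-class OOB permutation
  importances (percentage points) from a forest on all sites, re-training on
  sites with importance > 1.2, with OOB error reporting and prediction;
- **enrichment** — hypergeometric gene-set over-representation with
  Benjamini–Hochberg correction;
- **network** — provenance-annotated interaction networks over the
  class-specific proteins (mouse edges, human edges mapped through
  orthologues, "both" where supported twice, directed kinase→substrate
  overlay, hub ranking);
- **cnv** — median normalisation, duplicate-probe averaging, outlier
  smoothing, permutation-based circular binary segmentation, four-state
  calling (deletion < −0.5 ≤ neutral ≤ 0.5 < amplification ≤ 1.5 <
  high_amplification) and genome-wide level merging;
- **summarize** — hierarchical clustering (row-standardised, Euclidean,
  complete linkage), three-set overlap counts, kinase-class intensity sums,
  and >10-fold within-class screens;
- **synthdata** — simulators for both data types that plant class-specific
  effects, spike-ins, intensity-dependent missingness and focal
  amplifications, and emit the exact ground truth alongside.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
thresholds, enumeration/brute-force oracles, planted-truth recovery
experiments, determinism); the other modules have unit and property tests.

## CLI

Everything is reachable through one entry point:

```sh
# synthetic inputs with ground truth
phosphoflow simulate phospho --seed 1 --out data/
phosphoflow simulate acgh    --seed 1 --out data/

# stage by stage
phosphoflow preprocess --evidence data/evidence.tsv --spikeins data/spikeins.tsv \
    --classes data/classes.json --out run/
phosphoflow diff --matrix run/matrix_imputed.tsv --out run/contrasts.csv
phosphoflow signature train --matrix run/matrix_imputed.tsv --out run/signature.json
phosphoflow enrich --foreground fg.txt --background bg.txt --gmt sets.gmt --out enr.csv
phosphoflow network build --proteins p.txt --mouse-edges edges.tsv --out net/
phosphoflow cnv --probes data/probes.tsv --out cnv/
phosphoflow summarize cluster --matrix run/matrix_imputed.tsv --out clust.json

# end to end (YAML config, run manifest with checksums)
phosphoflow pipeline init-config --out run.yaml
phosphoflow pipeline run --config run.yaml --out run/
```

Exit codes: 0 ok, 1 validation error, 2 stage failure.

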