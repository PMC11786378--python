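# genediverse

Comparative characterization of gene groups (e.g. an "epigene" set
against all other protein-coding genes) across the structural and
functional axes that drive gene-level diversity:

- **gene structure** — gene/transcript lengths, exon counts,
  first/middle/last exon partitioning (canonical transcripts only);
- **isoform diversity** — tree-weighted mean intratissue Shannon
  entropy (bits) and mean intertissue Kullback–Leibler divergence of
  isoform-proportion profiles, with effective isoform counts (2^H);
- **sample weighting** — CLUSTALW-style similarity weights from a
  hierarchical sample tree combined with relative-expression weights;
- **protein complexes** — distinct complex counts, mean complex size,
  constitutive vs variable binding partners;
- **intrinsically disordered regions** — per-protein disordered
  fraction and maximum merged IDR length;
- **phenotype systems** — ontology ancestor closure mapping diseases to
  major body systems (direct children of a root phenotype term), with
  somatic/susceptibility filtering and inheritance-mode summaries;
- **expression specificity** — TPM renormalization, log10(x+1),
  median normalization, and weighted Tau;
- **temporal clustering** — developmental co-expression clustering per
  brain subregion with binned time weights and weighted Pearson
  correlation, plus cross-subregion metaclustering;
- **statistics** — contrast-set permutation tests (sampling the
  non-focal pool without replacement at focal-group size), two-sample
  proportion tests, Bonferroni correction, geometric means;
- **synthetic data** — generators for every input above with known
  ground truth (planted group shifts, true trees, trajectory classes,
  variable-partner counts) so the whole pipeline is testable offline.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: worked-example
exactness, brute-force oracle equivalence (1000 random instances per
operation), parameter recovery on synthetic data, and invariant suites
(duplicate-sample invariance, type-I error control).

## CLI

All stages are exposed under one entry point:

```sh
# generate a full set of synthetic inputs
genediverse simulate --seed 1 --n-genes 100 --out data/

# individual stages
genediverse structure --gtf data/annotation.gtf --labels data/labels.tsv --out structure.tsv
genediverse diversity --matrix data/isoforms.matrix.tsv --map data/isoforms.map.tsv \
    --tree data/tree.nwk --out diversity.tsv
genediverse test --features diversity.tsv --feature-col mean_entropy_bits \
    --labels data/labels.tsv --focal epigene --n-perm 1000
genediverse complexes --table data/complexes.tsv --labels data/labels.tsv --out cx.tsv
genediverse disorder --table data/disorder.tsv --labels data/labels.tsv --out idr.tsv
genediverse phenotype --ontology data/ontology.tsv --annotations data/diseases.tsv --out ph.tsv
genediverse tempclust --input data/temporal.tsv --labels data/labels.tsv --out clusters.tsv

# the whole pipeline from a config
genediverse run --config config.yaml
```

A minimal pipeline config:

```yaml
output_dir: out/
simulate:
  seed: 1
  n_genes: 100
  n_tissues: 6
params:
  n_perm: 1000
  seed: 1
```

The run writes per-stage TSVs, a `summary.tsv` with per-group summaries
and permutation p-values for eleven features, and a `manifest.json`
recording every seed and parameter needed to reproduce the run exactly.

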