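# syncytx

Spatial-transcriptomic and single-nucleus analysis toolkit for syncytial
organisms (e.g. acellular slime molds), built around fully synthetic,
ground-truthed data so every stage is testable offline.

The package covers four analysis tracks plus the machinery that feeds them:

- **`syncytx.simulate`** — seeded synthetic generators: an inhomogeneous
  hard-core nuclei point process with a fan/network split, rendered
  fluorescence-like images, gridded transcriptomes with region programs
  (fan / network / food-contact) and a traveling cyclic "mitotic wave", and
  sparse single-nucleus / amoeba UMI matrices at configurable depth.  Every
  generator returns a `SyntheticTruth` with the planted labels.
- **`syncytx.density`** — nuclei point-pattern analysis: shape statistics
  from label masks, exact nearest-neighbor distances, Gaussian-KDE density
  maps, an Otsu split of the y-axis density profile into fan and network
  bands, a Welch t-test on region densities, optimal-assignment scoring of
  detections (precision / accuracy), and a simple blob detector.
- **`syncytx.expression`** — expression-matrix machinery: TPM, thresholded
  log2-TPM, log-normalization (scale factor 10,000), depth and annotation
  filters, covariate-regression scaling with clipping, PCA, SNN-graph
  (Leiden) and Ward hierarchical clustering, one-vs-rest Wilcoxon marker
  detection (exact for small groups, tie-corrected normal approximation
  otherwise), expression-matched module scores, detected-gene overlaps, and
  q10/q90 display-contrast limits.
- **`syncytx.gridstats`** — grid-level statistics: region-vs-rest
  differential expression, per-specimen fan scoring with top-grid pooling,
  and the pairwise distance-versus-transcriptome-correlation regression.
- **`syncytx.mapping`** — pseudobulk averaging and the marker-restricted
  Spearman projection of nuclei clusters onto spatial clusters
  (column-then-row z-scaling, clipping to ±1, Ward dendrogram), plus
  per-grid correlation scores.
- **`syncytx.pseudotime`** — density-normalized diffusion-map embedding,
  block-wise pseudotime ranking along a group sequence, LOESS expression
  trends, and the mirrored pseudospatial ordering of grids.
- **`syncytx.io` / `syncytx.cli`** — plain-text readers/writers
  (MatrixMarket + TSV sidecars, gene × grid TSV, coordinate and point CSV,
  JSON truth files, Newick dendrograms), a strict run configuration, and a
  staged pipeline runner with a reproducibility manifest.

## Tests

```sh
python -m pytest -q tests/
```

The suite contains per-module unit tests with independent oracles
(brute-force nearest neighbors, exhaustive Otsu maximizer, LP assignment,
exact Wilcoxon enumeration, hand-rolled normal equations), property tests
(hypothesis), and `tests/test_acceptance.py` with one test per acceptance
criterion (oracle equivalence, closed forms, parameter recovery,
statistical calibration, planted-signal recovery, projection correctness,
wave recovery, engineering round-trips).

## CLI

```sh
syncytx run --seed 1 --outdir run          # simulate -> density -> grids ->
                                           # markers -> map -> wave
syncytx simulate --seed 1 --outdir run     # any stage runs its prerequisites
syncytx run --config config.yaml           # fully explicit, strict config
```

Every run writes `manifest.json` with the config, seed, parameter hash and
per-stage output hashes; identical config + seed reproduces identical
manifests (timings aside).

Example `config.yaml`:

```yaml
seed: 1
outdir: run
stages: [simulate, density, grids, markers, map, wave]
params:
  simulate: {n_genes: 1000, n_nuclei: 1000, program_log2fc: 1.0}
  density: {cell_size: 20.0}
  grids: {n_pcs: 10, cluster_method: hierarchical}
```

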