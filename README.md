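# breathsig

Discriminative metabolic signatures from online breath mass spectrometry.
The package implements a complete pipeline from raw time-resolved breath
recordings to annotated differential features:

- **`breathsig.synthdata`** — synthetic cohorts and raw recordings with
  known ground truth (planted differential features, isotopologue/adduct
  satellites, exhalation plateaus, batch factors), so every downstream
  stage is testable without external data.
- **`breathsig.preprocess`** — spectral preprocessing: resampling onto a
  0.0005 Th grid over m/z 50–500, TIC-based exhalation-window detection,
  exhalation-spectrum averaging, baseline-aware peak picking with
  trapezoidal integration, cross-sample feature alignment, TIC
  normalization and log2 transform into a breath-profile matrix.
- **`breathsig.diffstats`** — surrogate-variable analysis for latent
  batch/confounder structure, empirical-Bayes moderated t-tests,
  Benjamini–Hochberg adjustment, PCA scores, and cohort summary tests
  (pooled t from summaries, Fisher's exact, Mann–Whitney U).
- **`breathsig.classify`** — leakage-proof repeated stratified
  cross-validation: per-fold frozen SVA projection, training-only
  standardization, shadow-feature (Boruta-style) selection, linear SVM,
  vertically averaged ROC with bootstrap confidence bands.
- **`breathsig.annotate`** — monoisotopic-mass and adduct arithmetic, ppm
  matching against a bundled compound/pathway library, bounded molecular
  formula enumeration, isotope/adduct/loss satellite grouping, 1–5
  identification confidence levels, and permutation-based m/z-level
  pathway enrichment.

Recordings are read/written as plain scan-table TSV or a minimal profile
mzML dialect; matrices and libraries are TSV; ground truth is JSON.

## CLI

All stages are exposed under one `breathsig` entry point:

```sh
# generate a synthetic cohort (optionally raw recordings)
breathsig simulate --out-dir data/ --seed 7 --n-case 12 --n-control 12 \
    --n-features 200 --n-differential 30 --write-recordings

# raw recordings -> breath-profile matrix
breathsig preprocess --input-dir data/ --polarity pos --out matrix.tsv

# differential analysis with surrogate-variable adjustment
breathsig diffstats --matrix data/abundance.tsv --cohort data/cohort.tsv \
    --alpha 0.05 --sva on --out stats/

# cross-validated classification
breathsig classify --matrix data/abundance.tsv --cohort data/cohort.tsv \
    --repeats 10 --folds 10 --seed 1 --out cv/

# mass-based annotation + pathway enrichment
breathsig annotate --results stats/results.tsv --matrix data/abundance.tsv \
    --polarity pos --tol-ppm 15 --out annotation/
```

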