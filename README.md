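# radtex

Texture-analysis pipeline for discriminating lesions from normal tissue in
8-bit grayscale radiographs. The package implements the complete workflow:

1. **Synthetic study generation** (`radtex.synthetic_data`) — seeded
   panoramic-like radiographs with embedded elliptical lesions (abscess /
   cyst / tumor / normal) whose texture statistics differ per class, plus
   ground-truth annotation CSVs. Replaces non-redistributable clinical
   images so every stage is testable offline.
2. **Preprocessing** (`radtex.preprocess`) — Gaussian smoothing, 3×3 median
   filtering, percentile (imadjust-style) contrast stretching.
3. **ROI extraction** (`radtex.roi`) — fixed 40×40 windows around annotated
   lesion centers, plus a regional-maxima QA mask.
4. **Feature extraction** — three families:
   - `radtex.texture_glcm`: gray-level co-occurrence matrix, 13 features
     (energy, correlation, contrast, homogeneity, autocorrelation, cluster
     shade/prominence, dissimilarity, information measure of correlation,
     maximum probability, inverse-difference variants), angle-averaged;
   - `radtex.texture_glrlm`: gray-level run-length matrix, 7 features
     (SRE, LRE, GLN, RLN, RP, LGRE, HGRE), direction-averaged;
   - `radtex.wavelet`: orthonormal Haar filter-bank decomposition, 5
     statistics of the pooled detail coefficients (mean, sd, skewness,
     excess kurtosis, mean absolute deviation).
5. **Classification** (`radtex.classify`) — stratified hold-out split and a
   standardized RBF-kernel SVM.
6. **Evaluation** (`radtex.evaluation`) — confusion matrix, accuracy, MCC,
   sensitivity, specificity, PPV, and ROC/AUC (trapezoidal, tie-aware).

## Command line

A single entry point `radtex` orchestrates the stages:

```sh
radtex simulate    --out study/ --seed 7            # images + annotations.csv
radtex preprocess  --in study/ --out clean/ --sigma 1.0
radtex extract-roi --images clean/ --annotations study/annotations.csv \
                   --out rois/ --size 40
radtex features    --method glcm --rois rois/ \
                   --annotations study/annotations.csv --out features.csv
radtex train       --features features.csv --task lesion-vs-normal \
                   --split 0.667 --seed 7 --model model.joblib
radtex evaluate    --model model.joblib --features features.csv \
                   --report report.json --roc roc.csv
radtex run-all     --config config.yaml --out run/   # everything end to end
```

`simulate` and `run-all` accept a YAML config overriding any
`radtex.pipeline.PipelineConfig` field (class counts, image shape, feature
methods, split fraction, …). Exit codes: 0 success, 1 validation error,
2 runtime failure.

## Reproducibility notes

- Everything is deterministic under a fixed seed: regenerating a study,
  feature CSVs, and splits yields bit-identical artifacts.
- Class texture presets live in `radtex.synthetic_data.CLASS_PRESETS` and
  are tuned so the classes are separable by all three feature families
  (a contract asserted in the test suite), not to reproduce any published
  accuracy on real radiographs.
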