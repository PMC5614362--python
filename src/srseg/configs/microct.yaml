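# microCT-style run: model training on a high-contrast multiregion phantom.
# Filter/supervoxel/training parameters follow the microCT column of the
# optimised-parameter table (TV1, GC1, GN1, LG1, DG1, SV1, RF + appearance
# refinement); the TV clamp is omitted because the phantom's intensity
# range differs from the original instrument units.
name: microct_multiregion
seed: 7
input:
  phantom:
    kind: multiregion
    size: 64
    n_regions: 3
channels:
  - {name: tv1, operator: total_variation, params: {lambda_tv: 10, spacing_tv: [1, 1, 1], n_iter: 100}}
  - {name: gc1, operator: gaussian_centering, source: tv1, params: {sigma: 2}}
  - {name: gn1, operator: gaussian_normalization, source: tv1, params: {sigma: 2}}
  - {name: lg1, operator: log, source: tv1, params: {sigma_log: 2, thresh_flag: false, response: bright}}
  - {name: dg1, operator: dog, source: tv1, params: {sigma_init: 2, sigma_ratio: 1.6}}
supervoxels:
  source: tv1
  shape: [10, 10, 10]
  spacing: [1, 1, 1]
  compactness: 30
annotate:
  levels:
    - labels:
        - {name: background}
        - {name: body}
        - {name: core}
  strokes:
    # rough scribbles over large areas on three equally spaced slices
    - {level: 0, label: 0, mode: supervoxel, pen_width: 2,
       seeds: [[16, 4, 4], [16, 4, 59], [16, 59, 4], [16, 59, 59], [16, 32, 3], [16, 3, 32],
               [32, 4, 4], [32, 4, 59], [32, 59, 4], [32, 59, 59],
               [48, 4, 4], [48, 4, 59], [48, 59, 4], [48, 59, 59], [48, 32, 60], [48, 60, 32]]}
    - {level: 0, label: 1, mode: supervoxel, pen_width: 2,
       seeds: [[32, 32, 50], [32, 32, 14], [32, 50, 32], [32, 14, 32], [32, 45, 45], [32, 19, 19],
               [16, 32, 32], [16, 32, 40], [16, 40, 32], [16, 32, 24], [16, 24, 32],
               [48, 32, 32], [48, 32, 40], [48, 40, 32], [48, 32, 24], [48, 24, 32]]}
    - {level: 0, label: 2, mode: supervoxel, pen_width: 2,
       seeds: [[32, 32, 32], [32, 32, 36], [32, 36, 32], [32, 32, 28], [32, 28, 32],
               [28, 32, 32], [36, 32, 32]]}
train:
  predict_level: 0
  region: supervoxel
  sources: [tv1, gc1, gn1, lg1, dg1]
  classifier: ensemble_rf
  n_trees: 100
  refinement: appearance
  refine_lambda: 50
  confidence: 50
  rounds: 3
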