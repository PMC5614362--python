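# cryoSXT-style run: medium-SNR phantom with many varied blobs; TV4
# denoising, SV4 supervoxels and MV2 megavoxels from the cryoSXT column of
# the optimised-parameter table.  Model training is deliberately absent
# (it was not used for this regime); segmentation proceeds by super-region
# annotation, and the label splitter then classifies the objects.
name: cryosxt_cell
seed: 7
input:
  phantom:
    kind: organelle_cell
    size: 64
    n_blobs: 10
    snr: 3.0
channels:
  - {name: tv4, operator: total_variation, params: {lambda_tv: 7, spacing_tv: [1, 1, 1], n_iter: 100}}
supervoxels:
  source: tv4
  shape: [10, 10, 10]
  spacing: [1, 1, 1]
  compactness: 30
megavoxels:
  source: tv4
  lambda_mv: 0.4
  num_bins: 50
  gamma: null
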