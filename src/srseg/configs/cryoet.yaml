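# cryoET-style run: low-SNR organelle/tube phantom with the layered filter
# set (G1/G2 -> TV2/TV3 -> TH1/DG2/ST1), SV2 supervoxels and MV1 megavoxels
# from the cryoET column of the optimised-parameter table.  Annotation is
# interactive in the original workflow, so this config stops after the
# super-region hierarchy; scribbles can be supplied via annotate/train.
name: cryoet_organelles
seed: 7
input:
  phantom:
    kind: organelle_cell
    size: 64
    snr: 1.5
channels:
  - {name: g1, operator: gaussian, params: {sigma: 1}}
  - {name: g2, operator: gaussian, params: {sigma: 2}}
  - {name: tv2, operator: total_variation, source: g1, params: {lambda_tv: 7, spacing_tv: [1, 1, 1], n_iter: 200}}
  - {name: tv3, operator: total_variation, source: g2, params: {lambda_tv: 10, spacing_tv: [1, 1, 1], n_iter: 100}}
  - {name: th1, operator: threshold, source: tv3, params: {vmin: 0}}
  - {name: dg2, operator: dog, source: tv3, params: {sigma_init: 2, sigma_ratio: 1.6}}
  - {name: st1, operator: structure_tensor_det, source: tv3, params: {sigma1: 2, sigma_area: 2}}
supervoxels:
  source: tv3
  shape: [10, 10, 10]
  spacing: [1, 1, 1]
  compactness: 50
megavoxels:
  source: tv3
  lambda_mv: 0.1
  num_bins: 50
  gamma: auto
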