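# End-to-end demo: synthetic anchored-tissue phantom -> fluence
# normalization -> DoLD/AoLD maps -> orientation statistics.
seed: 11
phantom:
  width: 48
  height: 40
  field: {kind: pin, pins: [[8, 20], [39, 20]], blend_length: 10}
  iso: 1.0
  dichroic: 0.7
  noise_sigma: 0.05
  fluence: {0: 1.0, 45: 1.08, 90: 0.93, 135: 1.02}
dichroism:
  min_signal: 0.2
stats:
  n_bins: 18
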