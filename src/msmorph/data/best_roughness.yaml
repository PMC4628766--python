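features: ms
frame_ms: 100.0
deltas: 2
nb: 14
envelope_mode: hilbert
max_mod_freq: 240.0
n_acoustic_bands: 128
reduction: lda
g: 16
seed: 0
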