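dx_cm: 0.01
fraction: 0.2
gbar_1x: calibrated
nx: 100
ny: 100
pattern: vertical
seed: 7
species: human
stage: tissue
strip_length: 10
x_level: 1.0
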