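dx_cm: 0.01
fraction: 0.15
gbar_1x: calibrated
nx: 100
ny: 100
pattern: random
seed: 7
species: human
stage: tissue
x_level: 0.5
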