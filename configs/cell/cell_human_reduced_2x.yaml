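gNa_scale: 0.5
gbar_1x: calibrated
pacing_hz: 1.0
species: human
stage: cell
x_level: 2.0
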