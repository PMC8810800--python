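gbar_1x: calibrated
pacing_hz: 2.5
severity: none
stage: brugada
x_level: 0.0
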