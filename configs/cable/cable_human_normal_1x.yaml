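cell_length_um: 100.0
cell_radius_um: 10.0
gNa_scale: 1.0
gbar_1x: calibrated
n_cells: 100
ri_kohm_cm: 0.4
species: human
stage: cable
x_level: 1.0
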