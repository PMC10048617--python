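mean_height_per_cell: 3000.0
cv_peak: 2.4
lsae_sd: 0.25
dropout_shape: null
stutter: null
stutter_sr_sd: 0.02
drop_in_rate: 0.0164
drop_in_law: exponential
drop_in_scale: 400.0
drop_in_floor: 50.0
drop_in_cap: 5000.0
degradation: 1.0
size_ref: 125.0
inhibition: {}
saturation: 30000.0
call_floor: 46.0
baseline_sd: 4.0
trace_points: 200
cycles_note: 32-cycle direct amplification
seed: 0
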