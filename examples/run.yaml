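# End-to-end synthetic run: 60 NSR/AF records, heartbeat extraction,
# pace-variant encoder (d=16), mean aggregation, 10-fold CV.
seed: 0
out_dir: cyclebeat-run
n_records: 60
class_mix: [0.5, 0.5, 0.0, 0.0]
duration_s: 30.0
noise_sd: 0.02
slicing: beat
variant: pace
d: 16
epochs: 20
aggregation: mean
cv_folds: 10
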