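# Desk-scale end-to-end run: full 5-speed x 8-cycle protocol on a 150 Hz
# frame/analog clock (~2,000 training frames per fold), one fold trained.
synthetic:
  fs_analog: 150.0
  fps_us: 150.0
train:
  max_epochs: 5
train_folds: [1.00]
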