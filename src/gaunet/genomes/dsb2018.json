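{
  "n_blocks": 5,
  "first_filters": 8,
  "kernel_size": 7,
  "activation": 1,
  "pooling": 1,
  "batch_norm": 1,
  "dropout": 0,
  "optimizer": 4,
  "learning_rate": 5e-4,
  "batch_size": 16
}
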