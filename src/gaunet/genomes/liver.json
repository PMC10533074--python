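{
  "n_blocks": 7,
  "first_filters": 8,
  "kernel_size": 4,
  "activation": 1,
  "pooling": 1,
  "batch_norm": 1,
  "dropout": 0,
  "optimizer": 3,
  "learning_rate": 1e-4,
  "batch_size": 4
}
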