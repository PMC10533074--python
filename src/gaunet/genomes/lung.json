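{
  "n_blocks": 5,
  "first_filters": 8,
  "kernel_size": 5,
  "activation": 2,
  "pooling": 1,
  "batch_norm": 0,
  "dropout": 0,
  "optimizer": 3,
  "learning_rate": 1e-4,
  "batch_size": 8
}
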