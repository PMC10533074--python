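# ga-unet

Genetic-algorithm design of compact U-shaped segmentation networks for
biomedical images.

Hand-designed encoder–decoder networks such as U-Net segment organs and
nuclei well, but carry tens of millions of parameters. This package
searches, with a simple elitist genetic algorithm, a compact space of
U-shaped architectures and training recipes, and routinely finds networks
with two to three orders of magnitude fewer parameters that remain
trainable to competitive accuracy. It is aimed at researchers who want
small, deployable segmentation models or a transparent, dependency-light
testbed for evolutionary architecture search.

## The method

A candidate is a 10-gene vector

```
(B, C, F, A, P, BN, D, O, LR, BA)
```

- `B` — total blocks (encoder + bottleneck + decoder). The network is
  symmetric with one bottleneck block, so `B = 2d + 1` is odd and `d` is
  the depth.
- `C` — filters in the first block; channels double at every level
  (`C, 2C, …, C·2^d` at the bottleneck) and halve back up.
- `F` — square kernel size; `A` — activation (ReLU / ELU / LeakyReLU);
  `P` — 2×2 stride-2 pooling (max / average); `BN`, `D` — batch
  normalization and dropout (rate 0.3) switches; `O` — optimizer (SGD /
  RMSprop / Adam / Adamax); `LR ∈ [10⁻⁴, 10⁻³]`; `BA` — batch size.

Each block is two same-padded `F×F` convolutions (each optionally BN, then
activation); skip connections concatenate encoder features into the
same-level decoder; up-sampling is a learned 2×2 stride-2 transposed
convolution; the head is a 1×1 convolution with sigmoid.

The GA evaluates each genome by training its decoded network briefly with
its own recipe under the soft Dice loss

```
Dice_loss(X, Y) = 1 − 2|X ∩ Y| / (|X| + |Y|)
```

and scoring validation pixel accuracy as fitness. Each generation keeps the
`K` best parents, breeds `2(K−1)` offspring from successive parent pairs by
single-point crossover and per-gene mutation, and fills the next population
with the elites plus the best offspring, so the best fitness never
decreases. Evaluation metrics (ACC, PRE, REC, DSC, IoU, pixel-wise AUC) and
exact per-layer parameter accounting are included, along with a seeded
generator of organ-like phantoms (elliptical blobs with paired binary
masks) so everything runs without external data. Networks are built and
trained on a small self-contained numpy engine with exact backpropagation —
no deep-learning framework required.

## Worked example

Count the parameters of the packaged lung-segmentation genome
(B=5, C=8, 5×5 kernels, ELU, max-pooling, Adam):

```sh
$ ga-unet params src/gaunet/genomes/lung.json --channels 1
76,553
0.076
```

76,553 total parameters, printed also in truncated millions — 0.24% of the
31,030,593-parameter original U-Net baseline
(`ga-unet params --baseline-unet`). A short search on 60 synthetic 64×64
phantoms:

```sh
$ ga-unet search --synthetic --n-images 60 --population 4 --k-best 2 \
    --generations 2 --epochs-per-eval 2 --seed 5 --out run/
generation 0: best=0.6354 mean=0.4746
generation 1: best=0.9005 mean=0.7017
best fitness 0.9005; artifacts in run/
```

Each line reports the best and mean validation pixel accuracy of the
population after that generation; `run/` receives `best_genome.json`, the
per-generation `search_log.csv`, and the retrained winner's weights. The
same can be done from Python:

```python
from gaunet import GAConfig, SyntheticConfig, generate_dataset, split_dataset, run_search

images, masks = generate_dataset(SyntheticConfig(n_images=60, seed=11))
split = split_dataset(60, seed=11)
cfg = GAConfig(population_size=4, generations=2, n_best_parents=2,
               epochs_per_eval=2, master_seed=5)
best, log = run_search(cfg,
                       (images[list(split.train)], masks[list(split.train)]),
                       (images[list(split.validation)], masks[list(split.validation)]))
print(best.fitness, best.genome)
```

Other commands: `ga-unet decode` (layer plan + parameter table),
`ga-unet train` / `ga-unet evaluate` (final training and the metrics
report), `ga-unet synth` (write a phantom dataset to disk).

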