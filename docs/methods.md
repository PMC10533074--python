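# Methods

## Search space and genome

A candidate architecture-plus-recipe is the integer/real vector
`(B, C, F, A, P, BN, D, O, LR, BA)` with domains: blocks `B ∈ [3, 7]`,
first-block filters `C ∈ {2, 4, 8}`, kernel `F ∈ [3, 7]`, activation
`A ∈ {1, 2, 3}` (ReLU, ELU α=1, LeakyReLU slope 0.3), pooling `P ∈ {1, 2}`
(max, average; both 2×2 stride 2), `BN, D ∈ {0, 1}` (dropout rate 0.3),
optimizer `O ∈ {1..4}` (SGD, RMSprop, Adam, Adamax), learning rate
`LR ∈ [10⁻⁴, 10⁻³]`, batch size `BA ∈ {4, 8, 16, 32}`.

Because the network has `d` encoder blocks, one bottleneck and `d` mirrored
decoder blocks, `B = 2d + 1` must be odd. The effective block values are
therefore `{3, 5, 7}`; an even draw or variation result is repaired by
decrementing. `LR` is treated as continuous and sampled log-uniformly, a
natural prior for learning rates spanning an order of magnitude. Repair of
arbitrary vectors snaps each discrete gene to the nearest domain value with
ties broken toward the smaller value — a deliberate bias toward cheaper
architectures, in keeping with the complexity-limiting goal — and clamps
`LR` into its interval.

## Decoding and parameter accounting

Each block is two same-padded `F×F` convolutions; when `BN=1` a batch-norm
layer sits between each convolution and its activation; dropout, when
enabled, follows the block's second activation (block-level placement keeps
the block abstraction intact and adds no parameters). Channel widths double
down the encoder from `C` and halve up the decoder; skip connections
concatenate the same-level encoder output ahead of the decoder block's two
convolutions. Up-sampling is a learned 2×2 stride-2 transposed convolution:
a parameter-free upsampler cannot reproduce the published complexity
figures, while the transposed-convolution reading reproduces all of them.

Closed-form counts: `k×k` convolution `cin→cout` has `k²·cin·cout + cout`
parameters; the 2×2 transposed convolution has `4·cin·cout + cout`;
batch norm over `c` channels has `4c` (scale, shift, running mean and
variance — the *total*-parameter convention, which is the one consistent
with the liver network's printed 0.207 M figure; the trainable-only
convention gives 0.206); pooling, activations, concatenation and dropout
have none; the 1×1 head has `cin·n_classes + n_classes`. Millions figures
are *truncated*, not rounded (148,825 prints as 0.148, not 0.149), as are
the percentage ratios against the 31,030,593-parameter baseline U-Net
(4 levels at 64–512 channels, bottleneck 1024, two 3×3 convolutions per
block, no BN).

Input channels are 1 for CT-like grayscale data and 3 for RGB microscopy;
the packaged DSB 2018 genome only reproduces its printed count at 3
channels, the lung/liver genomes at 1. Same-size padding is used
everywhere; even kernels (4×4, 6×6) pad asymmetrically with the extra pixel
at the bottom/right.

## The evolutionary loop

Defaults: population `L=10`, generations `G=5`, elites `K=5`, crossover
rate 0.5, mutation rate 0.1, 20 training epochs per fitness evaluation.
Fitness is validation pixel accuracy at threshold 0.5 after short training
with the genome's own optimizer, learning rate and batch size. Offspring
come from successive overlapping elite pairs — (1,2), (2,3), …, (K−1,K) —
each pair undergoing single-point crossover (cut uniform in {1..9}, tails
swapped, children repaired); mutation then resamples each gene
independently with probability equal to the mutation rate (log-uniformly
for `LR`). This per-gene reading keeps every gene reachable and maintains
population diversity; a literal last-gene-only perturbation would only ever
touch the batch size. Environmental selection keeps the `K` elites of the
current population plus the best `L−K` offspring, conserving population
size; elites retain their cached fitness rather than being retrained, which
makes the per-generation best fitness non-decreasing by construction and
avoids stochastic-retraining regressions. All ordering ties break toward
the smaller (earlier-created) individual id for reproducibility.

Seeding: the master seed spawns independent streams for initialization and
the variation operators; each individual's training seed is derived from a
stable hash of its genome, so identical genomes always train identically
within a run. A training divergence (non-finite loss) degrades that
individual's fitness to 0.0 with a warning instead of aborting the search.

## Losses and metrics

Training minimizes the soft Dice loss
`1 − (2Σpy + ε)/(Σp + Σy + ε)` with smoothing `ε = 1` in numerator and
denominator; the smoothing keeps the all-background case defined and the
gradient bounded. The reported Dice coefficient itself is unsmoothed.
Reported metrics are pixel accuracy, precision, recall, DSC, IoU (all at
threshold 0.5) and pixel-wise ROC AUC on raw probabilities (pooled within
an image; batch reports average over images). Degenerate denominators
return 0.0 with a warning (DSC/IoU of two empty masks is 1.0, the limit of
perfect agreement; AUC of single-class truth is 0.5). On binary masks,
Dice loss (ε→0) complements DSC, and `DSC = 2·IoU/(1 + IoU)` identically.

## The numpy network engine

Networks are built and trained on a small self-contained engine:
convolutions via im2col + BLAS matmul with exact backward passes,
transposed convolution, batch norm (momentum 0.99, ε=10⁻³), 2×2 pooling,
inverted dropout, and the four optimizers with their conventional
moment-decay defaults (β₁=0.9, β₂=0.999, ρ=0.9, ε=10⁻⁷). Weights are
Glorot-uniform from a seeded generator; biases start at zero. Every layer's
gradients are verified against central finite differences in the test
suite, and the engine's allocated-parameter total is required to equal the
analytic layer-plan count for randomly drawn genomes — two independent
routes to the same number. Computation is float32; gradient checks run in
float64.

## Synthetic phantoms

The generator emulates binary organ/nuclei segmentation data: each mask is
a union of 2–5 randomly placed and oriented filled ellipses with semi-axes
6–16 px; the image is 0.8 on the mask and 0.2 elsewhere plus clipped
Gaussian noise (σ=0.05). Defaults are 60 images of 64×64 — small enough
that a full search runs on one CPU in minutes, and divisible by 8 so the
deepest decodable network fits; size, blob geometry, contrast, noise and
channel count (1 or 3) are configurable. Splits are 20% test and 10% of the
remaining training portion for validation (floored, at least one image),
shuffled by seed. Images round-trip through 8-bit PNG (masks stored 0/255).

What the phantoms do *not* emulate: anatomical texture, intensity
inhomogeneity, unclear organ boundaries, correlated noise, or the size
statistics of real CT/microscopy data. Passing tests therefore demonstrate
that the search loop, decoder, engine and metrics are correct and that the
pipeline can learn a well-posed segmentation task — not that any discovered
architecture transfers to clinical data. Real datasets in the same
`images/ + masks/` PNG layout are accepted transparently.

## Problem sizes and numerical choices

Desk-scale defaults used throughout the tests and examples: searches of
L=4–10 over 1–10 generations with 1–2 training epochs per evaluation on
60 phantoms at 64×64, and 10-epoch final trainings — sizes chosen so the
full pipeline, including property-based checks, runs comfortably on a
single CPU while still exercising every code path at real (if small)
scale. The published-search setting (L=10, G=5, K=5, 20 epochs/eval) is
the library default.

Known limitations: single-class sigmoid heads only (no multi-class
softmax); 2D only; no data augmentation (deliberate: the target data are
described as clean enough not to need preprocessing); fitness evaluation is
sequential, not parallel; batch-norm statistics after very short fitness
trainings are noisy, which is shared by any short-budget evaluation scheme.
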