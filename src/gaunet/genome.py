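"""Search space and genome encoding for the architecture search.

A candidate network plus its training recipe is encoded as a 10-gene
vector (B, C, F, A, P, BN, D, O, LR, BA):

======  ==========================  =========================
gene    meaning                     domain (default space)
======  ==========================  =========================
B       total number of blocks      odd values in [3, 7]
C       filters in the first block  {2, 4, 8}
F       square kernel size          [3, 7]
A       activation code             1=ReLU, 2=ELU, 3=LeakyReLU
P       pooling code                1=max, 2=average (2x2, stride 2)
BN      batch normalization         {0, 1}
D       dropout (rate 0.3)          {0, 1}
O       optimizer code              1=SGD, 2=RMSprop, 3=Adam, 4=Adamax
LR      learning rate               [1e-4, 1e-3], log-uniform
BA      mini-batch size             {4, 8, 16, 32}
======  ==========================  =========================

Because the network is U-shaped with ``d`` encoder blocks, one bottleneck
block and ``d`` mirrored decoder blocks, the total block count ``B = 2d + 1``
must be odd; even values produced by sampling or variation operators are
repaired by decrementing.
"""

from __future__ import annotations

import dataclasses
import json
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .errors import ConfigurationError, GenomeError

__all__ = [
    "GENE_NAMES",
    "ACTIVATION_NAMES",
    "POOLING_NAMES",
    "OPTIMIZER_NAMES",
    "DROPOUT_RATE",
    "SearchSpace",
    "Genome",
    "Individual",
    "sample_genome",
    "repair_genome",
    "validate_genome",
    "genome_to_json",
    "genome_from_json",
    "save_genome",
    "load_genome",
    "load_builtin",
]

GENE_NAMES: tuple[str, ...] = (
    "n_blocks",
    "first_filters",
    "kernel_size",
    "activation",
    "pooling",
    "batch_norm",
    "dropout",
    "optimizer",
    "learning_rate",
    "batch_size",
)

ACTIVATION_NAMES = {1: "relu", 2: "elu", 3: "leaky_relu"}
POOLING_NAMES = {1: "max", 2: "average"}
OPTIMIZER_NAMES = {1: "sgd", 2: "rmsprop", 3: "adam", 4: "adamax"}

#: drop probability used whenever the dropout gene is switched on
DROPOUT_RATE = 0.3


@dataclasses.dataclass(frozen=True)
class SearchSpace:
    """Domains of the ten genes; defaults span the full search space."""

    blocks_domain: tuple[int, ...] = (3, 4, 5, 6, 7)
    filters_domain: tuple[int, ...] = (2, 4, 8)
    kernel_domain: tuple[int, ...] = (3, 4, 5, 6, 7)
    activation_domain: tuple[int, ...] = (1, 2, 3)
    pooling_domain: tuple[int, ...] = (1, 2)
    bn_domain: tuple[int, ...] = (0, 1)
    dropout_domain: tuple[int, ...] = (0, 1)
    optimizer_domain: tuple[int, ...] = (1, 2, 3, 4)
    lr_range: tuple[float, float] = (1e-4, 1e-3)
    batch_domain: tuple[int, ...] = (4, 8, 16, 32)

    def __post_init__(self) -> None:
        for name in (
            "blocks_domain",
            "filters_domain",
            "kernel_domain",
            "activation_domain",
            "pooling_domain",
            "bn_domain",
            "dropout_domain",
            "optimizer_domain",
            "batch_domain",
        ):
            dom = getattr(self, name)
            if len(dom) == 0:
                raise ConfigurationError(f"empty domain: {name}")
        lo, hi = self.lr_range
        if not (0.0 < lo <= hi):
            raise ConfigurationError(
                f"lr_range must satisfy 0 < lo <= hi, got ({lo}, {hi})"
            )
        if not any(b % 2 == 1 for b in self.blocks_domain):
            raise ConfigurationError("blocks_domain contains no odd value")


@dataclasses.dataclass(frozen=True)
class Genome:
    """One point of the search space: an architecture plus training recipe."""

    n_blocks: int
    first_filters: int
    kernel_size: int
    activation: int
    pooling: int
    batch_norm: int
    dropout: int
    optimizer: int
    learning_rate: float
    batch_size: int

    @property
    def depth(self) -> int:
        """Number of encoder (= decoder) levels, ``d = (B - 1) / 2``."""
        return (self.n_blocks - 1) // 2

    def to_vector(self) -> list[float]:
        return [getattr(self, name) for name in GENE_NAMES]

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "Genome":
        if len(vec) != len(GENE_NAMES):
            raise GenomeError(
                f"genome vector must have {len(GENE_NAMES)} genes, got {len(vec)}"
            )
        kwargs = dict(zip(GENE_NAMES, vec))
        for name in GENE_NAMES:
            if name != "learning_rate":
                kwargs[name] = int(kwargs[name])
        kwargs["learning_rate"] = float(kwargs["learning_rate"])
        return cls(**kwargs)


@dataclasses.dataclass
class Individual:
    """A genome with a cached fitness and a creation-order id."""

    genome: Genome
    fitness: Optional[float] = None
    id: int = 0

    def has_fitness(self) -> bool:
        return self.fitness is not None


def validate_genome(g: Genome, space: Optional[SearchSpace] = None) -> None:
    """Raise :class:`GenomeError` unless every gene lies in its domain and B is odd."""
    space = space or SearchSpace()
    if g.n_blocks % 2 != 1:
        raise GenomeError(f"n_blocks must be odd (2d+1 blocks), got {g.n_blocks}")
    checks = [
        ("n_blocks", g.n_blocks, space.blocks_domain),
        ("first_filters", g.first_filters, space.filters_domain),
        ("kernel_size", g.kernel_size, space.kernel_domain),
        ("activation", g.activation, space.activation_domain),
        ("pooling", g.pooling, space.pooling_domain),
        ("batch_norm", g.batch_norm, space.bn_domain),
        ("dropout", g.dropout, space.dropout_domain),
        ("optimizer", g.optimizer, space.optimizer_domain),
        ("batch_size", g.batch_size, space.batch_domain),
    ]
    for name, value, domain in checks:
        if value not in domain:
            raise GenomeError(f"{name}={value} outside domain {sorted(domain)}")
    lo, hi = space.lr_range
    if not (lo <= g.learning_rate <= hi):
        raise GenomeError(
            f"learning_rate={g.learning_rate} outside [{lo}, {hi}]"
        )


def sample_genome(space: SearchSpace, rng: np.random.Generator) -> Genome:
    """Draw a uniformly random valid genome.

    Discrete genes are uniform over their domains (an even block draw is
    decremented to the next odd count); the learning rate is log-uniform
    over ``lr_range``.
    """
    if not isinstance(space, SearchSpace):
        raise ConfigurationError("space must be a SearchSpace")

    def pick(domain: tuple[int, ...]) -> int:
        return int(rng.choice(np.asarray(sorted(domain))))

    b = pick(space.blocks_domain)
    if b % 2 == 0:
        b -= 1
    lo, hi = space.lr_range
    lr = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
    g = Genome(
        n_blocks=b,
        first_filters=pick(space.filters_domain),
        kernel_size=pick(space.kernel_domain),
        activation=pick(space.activation_domain),
        pooling=pick(space.pooling_domain),
        batch_norm=pick(space.bn_domain),
        dropout=pick(space.dropout_domain),
        optimizer=pick(space.optimizer_domain),
        learning_rate=min(max(lr, lo), hi),
        batch_size=pick(space.batch_domain),
    )
    validate_genome(g, space)
    return g


def _snap(value: float, domain: Iterable[int]) -> int:
    """Nearest allowed value; ties broken toward the smaller one."""
    return min(sorted(domain), key=lambda d: (abs(value - d), d))


def repair_genome(
    vec: Sequence[float], space: Optional[SearchSpace] = None
) -> Genome:
    """Map an arbitrary finite 10-vector onto a valid :class:`Genome`.

    Discrete genes are snapped to the nearest domain value (ties toward the
    smaller value), an even block count is decremented by one, and the
    learning rate is clamped to ``lr_range``.
    """
    space = space or SearchSpace()
    if len(vec) != len(GENE_NAMES):
        raise GenomeError(
            f"genome vector must have {len(GENE_NAMES)} genes, got {len(vec)}"
        )
    vals = [float(v) for v in vec]
    if not all(math.isfinite(v) for v in vals):
        raise GenomeError("genome vector contains non-finite values")

    b = _snap(vals[0], space.blocks_domain)
    if b % 2 == 0:
        candidate = b - 1
        odd = [v for v in space.blocks_domain if v % 2 == 1]
        b = candidate if candidate in space.blocks_domain else _snap(candidate, odd)
    lo, hi = space.lr_range
    g = Genome(
        n_blocks=b,
        first_filters=_snap(vals[1], space.filters_domain),
        kernel_size=_snap(vals[2], space.kernel_domain),
        activation=_snap(vals[3], space.activation_domain),
        pooling=_snap(vals[4], space.pooling_domain),
        batch_norm=_snap(vals[5], space.bn_domain),
        dropout=_snap(vals[6], space.dropout_domain),
        optimizer=_snap(vals[7], space.optimizer_domain),
        learning_rate=min(max(vals[8], lo), hi),
        batch_size=_snap(vals[9], space.batch_domain),
    )
    validate_genome(g, space)
    return g


# ---------------------------------------------------------------------------
# JSON serialization


def genome_to_json(g: Genome) -> str:
    return json.dumps(dataclasses.asdict(g), indent=2)


def genome_from_json(text: str) -> Genome:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GenomeError(f"malformed genome JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise GenomeError("genome JSON must be an object")
    missing = [name for name in GENE_NAMES if name not in payload]
    if missing:
        raise GenomeError(f"missing gene key: {missing[0]!r}")
    return Genome(
        **{
            name: (float(payload[name]) if name == "learning_rate" else int(payload[name]))
            for name in GENE_NAMES
        }
    )


def save_genome(g: Genome, path: Union[str, Path]) -> None:
    Path(path).write_text(genome_to_json(g) + "\n")


def load_genome(path: Union[str, Path]) -> Genome:
    return genome_from_json(Path(path).read_text())


def load_builtin(name: str) -> Genome:
    """Load one of the packaged discovered genomes: lung, dsb2018 or liver."""
    ref = resources.files("gaunet").joinpath(f"genomes/{name}.json")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise GenomeError(
            f"unknown builtin genome {name!r}; available: lung, dsb2018, liver"
        ) from exc
    return genome_from_json(text)
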