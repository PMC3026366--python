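"""Synthetic Boolean-network models and time-series generation.

Random networks with bounded in-degree and uniform random truth tables are
updated synchronously: gene j at time t+1 is its truth table applied to its
parents' states at t (or, with per-edge delays, at t+1−d).  An independent
flip with probability ``noise`` is then applied to every updated symbol and
the flipped state feeds the next update, so the dynamics form an ergodic
Markov chain for noise > 0.  All randomness is driven by explicit seeds;
identical (seed, parameters) reproduce every output bit.

This generator emulates the *shape* of Boolean-quantized time-series
expression data (the substrate of all metrics here); it makes no attempt at
kinetic realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import GeneNetwork
from .preprocess import BinaryExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BooleanNetworkModel",
    "random_network",
    "simulate_series",
    "saturation_dataset",
    "informative_dataset",
    "expression_series",
]


@dataclass
class BooleanNetworkModel:
    """A Boolean GRN: per-gene parent sets, truth tables, delays, flip noise."""

    gene_ids: list[str]
    parents: list[tuple[int, ...]]          # regulator indices per gene
    tables: list[np.ndarray]                # truth table of length 2^k per gene
    delays: list[tuple[int, ...]] = None    # per-parent delay (≥ 1), defaults to 1
    noise: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if len(self.parents) != n or len(self.tables) != n:
            raise ValidationError("parents/tables must have one entry per gene")
        if self.delays is None:
            self.delays = [tuple(1 for _ in p) for p in self.parents]
        if not 0.0 <= self.noise < 0.5:
            raise ValidationError("noise must lie in [0, 0.5)")
        for g, (p, tab, d) in enumerate(zip(self.parents, self.tables, self.delays)):
            if g in p:
                raise ValidationError(f"gene {g} regulates itself")
            if len(tab) != 2 ** len(p):
                raise ValidationError(f"gene {g}: truth table size {len(tab)} != 2^{len(p)}")
            if len(d) != len(p) or any(di < 1 for di in d):
                raise ValidationError(f"gene {g}: bad delay vector {d}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def max_delay(self) -> int:
        return max((d for ds in self.delays for d in ds), default=1)

    def network(self) -> GeneNetwork:
        """True regulator→target edge set of the model."""
        edges = {
            (self.gene_ids[i], self.gene_ids[j])
            for j, ps in enumerate(self.parents)
            for i in ps
        }
        return GeneNetwork(tuple(self.gene_ids), frozenset(edges))


def random_network(
    n: int,
    max_in_degree: int = 3,
    edge_density: float = 0.5,
    noise: float = 0.05,
    seed: int | np.random.SeedSequence | None = None,
    edge_delay_max: int = 1,
) -> BooleanNetworkModel:
    """Draw a random Boolean GRN.

    Each gene's in-degree is Binomial(max_in_degree, edge_density); parents
    are sampled uniformly without replacement excluding the gene itself, and
    truth tables uniformly over all Boolean functions of the parents.  With
    ``edge_delay_max`` > 1 each edge gets a uniform integer delay in
    [1, edge_delay_max], giving data with true multi-step regulatory lags.
    """
    if n < 2:
        raise ValidationError("need at least 2 genes")
    if not 1 <= max_in_degree <= n - 1:
        raise ValidationError(f"max_in_degree must lie in [1, {n - 1}]")
    if not 0.0 <= edge_density <= 1.0:
        raise ValidationError("edge_density must lie in [0, 1]")
    if edge_delay_max < 1:
        raise ValidationError("edge_delay_max must be ≥ 1")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1}" for i in range(n)]
    parents, tables, delays = [], [], []
    for j in range(n):
        k = int(rng.binomial(max_in_degree, edge_density))
        pool = [i for i in range(n) if i != j]
        p = tuple(sorted(int(x) for x in rng.choice(pool, size=k, replace=False)))
        parents.append(p)
        tables.append(rng.integers(0, 2, size=2 ** k, dtype=np.int8))
        delays.append(tuple(int(d) for d in rng.integers(1, edge_delay_max + 1, size=k)))
    return BooleanNetworkModel(gene_ids, parents, tables, delays, noise)


def simulate_series(
    model: BooleanNetworkModel,
    m: int,
    seed: int | np.random.SeedSequence | None = None,
) -> BinaryExpressionMatrix:
    """Simulate an n × m binary time series from the model.

    The first max-delay columns are uniform random initial states; each later
    column is the synchronous truth-table update followed by independent
    symbol flips with probability ``model.noise`` (process noise: the flipped
    state is what downstream genes see).
    """
    if m < 2:
        raise ValidationError("need at least 2 time points")
    rng = np.random.default_rng(seed)
    n, d0 = model.n_genes, model.max_delay
    x = np.zeros((n, m), dtype=np.int8)
    init = min(d0, m)
    x[:, :init] = rng.integers(0, 2, size=(n, init), dtype=np.int8)
    for t in range(init, m):
        for j in range(n):
            p, d = model.parents[j], model.delays[j]
            if p:
                idx = 0
                for i, di in zip(p, d):
                    idx = (idx << 1) | int(x[i, t - di])
                x[j, t] = model.tables[j][idx]
            else:
                x[j, t] = model.tables[j][0]
        if model.noise > 0.0:
            flips = rng.random(n) < model.noise
            x[flips, t] ^= 1
    return BinaryExpressionMatrix(list(model.gene_ids), x)


def saturation_dataset(
    n: int,
    m_max: int,
    seed: int | None = None,
    max_in_degree: int = 3,
    edge_density: float = 0.5,
    noise: float = 0.05,
    edge_delay_max: int = 1,
) -> tuple[BooleanNetworkModel, BinaryExpressionMatrix]:
    """One network plus one long series, intended for prefix sweeps.

    A prefix of the returned matrix equals its leading columns exactly, so
    data-size studies (15, 20, … time points) reuse a single trajectory.
    """
    if m_max < 15:
        raise ValidationError("saturation studies need at least 15 time points")
    ss = np.random.SeedSequence(seed)
    net_seed, series_seed = ss.spawn(2)
    model = random_network(
        n, max_in_degree, edge_density, noise, net_seed, edge_delay_max
    )
    series = simulate_series(model, m_max, series_seed)
    return model, series


def expression_series(
    model: BooleanNetworkModel,
    m: int,
    seed: int | np.random.SeedSequence | None = None,
    on_level: float = 1.0,
    off_level: float = 0.0,
    obs_noise_sd: float = 0.4,
):
    """Continuous microarray-like readout of a simulated Boolean trajectory.

    The Boolean dynamics are simulated as in :func:`simulate_series`; each
    cell is then observed as the ON/OFF expression level plus independent
    Gaussian measurement noise.  Feeding the result through the standard
    imputation/quantization pipeline reproduces the shape of real
    median-binarized expression data — in particular, the full-series
    trimmed-median split drives every gene's binary marginal toward balance,
    the mechanism behind entropy rising (and pairwise MI estimates falling)
    as more time points are used.

    ``obs_noise_sd`` defaults to 0.4 of the ON−OFF dynamic range, mid-range
    for microarray readout variability.

    Returns an :class:`~tlgrn.io.ExpressionMatrix` (continuous, no missing
    values); quantize it with :func:`~tlgrn.preprocess.binarize`.
    """
    from .io import ExpressionMatrix

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    series_seed, obs_seed = ss.spawn(2)
    states = simulate_series(model, m, series_seed)
    rng = np.random.default_rng(obs_seed)
    levels = off_level + (on_level - off_level) * states.values.astype(float)
    observed = levels + rng.normal(0.0, obs_noise_sd, size=levels.shape)
    return ExpressionMatrix(list(model.gene_ids), observed)


def informative_dataset(
    n: int,
    m: int,
    seed: int | None = None,
    min_dynamic_fraction: float = 0.5,
    min_row_entropy: float = 0.5,
    min_distinct_patterns: int = 4,
    max_draws: int = 512,
    **model_kwargs,
) -> tuple[BooleanNetworkModel, BinaryExpressionMatrix]:
    """Draw (model, series) pairs until the series is dynamically informative.

    Noiseless Boolean dynamics often degenerate in ways that make the wiring
    unrecoverable by any method: collapse to a fixed point (constant rows
    carry no signal), or synchronization into a shared attractor cycle where
    rows duplicate each other — duplicated regulators are informationally
    interchangeable, so no data-driven scheme can attribute the regulation.
    Parameter-recovery studies therefore condition on identifiable data:
    instances are drawn from the seeded stream until (a) at least
    ``min_dynamic_fraction`` of the gene rows show sustained variation (row
    entropy ≥ ``min_row_entropy`` bits over the whole series), (b) the
    dynamic rows are pairwise distinct up to complementation, and (c) they
    realize at least ``min_distinct_patterns`` distinct patterns.  The
    first such instance is used; fully deterministic given the seed.
    """
    from .infotheory import entropy

    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max_draws):
        net_seed, series_seed = child.spawn(2)
        model = random_network(n, seed=net_seed, **model_kwargs)
        series = simulate_series(model, m, series_seed)
        dynamic = [
            i for i in range(n) if entropy(series.values[i]) >= min_row_entropy
        ]
        if len(dynamic) < min_dynamic_fraction * n:
            continue
        patterns = set()
        for i in dynamic:
            row = tuple(int(v) for v in series.values[i])
            complement = tuple(1 - v for v in row)
            patterns.add(min(row, complement))
        if len(patterns) != len(dynamic) or len(patterns) < min_distinct_patterns:
            continue
        return model, series
    raise ValidationError(
        f"no informative instance found in {max_draws} draws; "
        "relax min_dynamic_fraction or change parameters"
    )
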