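"""Synthetic two-condition RNA-seq experiments with controlled composition bias.

The generator mirrors the sampling model the estimator targets.  Each gene g
has a true expression level ``mu_{g,z}`` per condition z (gene length is
absorbed into mu and not simulated separately).  The total RNA output of a
condition is ``S_z = sum_g mu_{g,z}``; a library of target depth ``N_k``
then observes

    Y_gk ~ Poisson( mu_{g,z(k)} / S_z(k) * N_k )

so reads measure proportions of the condition's RNA pool, and any asymmetry
in that pool (genes unique to one condition, one-sided differential
expression) biases the proportions of every other gene — exactly the
composition bias TMM is built to remove.

Base expression values are drawn either from a user-supplied empirical count
column (resampled with replacement, mimicking a real count distribution) or
from a heavy-tailed parametric fallback (exponentiated normal on the natural
log scale, log-sd 2 by default), which preserves the strong right skew of
real RNA-seq counts without shipping external data.

The returned :class:`SimulatedExperiment` carries the full ground truth:
per-gene expression in both conditions, DE and uniqueness labels, the true
outputs ``S_1, S_2``, and the true production ratio / normalization factor
in the orientation used by :mod:`tmmnorm.tmm_core` (condition 1 plays the
sample k, condition 2 the reference r).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .count_io import CountMatrix

__all__ = [
    "SimConfig",
    "SimulatedExperiment",
    "build_source",
    "simulate_experiment",
    "true_factor",
]

Sampler = Callable[[np.random.Generator, int], np.ndarray]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated experiment.

    Defaults follow the package's standard composition-bias scenario:
    10,000 genes shared between conditions, 10% as many genes expressed only
    in condition 1, 5% of the shared genes DE at 2-fold with 80% of the DE
    higher in condition 1, one library per condition at a million reads.
    """

    n_common: int = 10_000
    n_unique_1: int = 1_000
    n_unique_2: int = 0
    prop_de: float = 0.05
    fold_change: float = 2.0
    prop_de_up_1: float = 0.8
    library_sizes: float | Sequence[float] = 1_000_000
    n_reps: int = 1
    seed: int | None = None
    empirical: np.ndarray | None = None  # observed counts to resample, optional
    log_mean: float = 4.0  # natural-log scale of the parametric fallback
    log_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_common < 0 or self.n_unique_1 < 0 or self.n_unique_2 < 0:
            raise ValueError("gene counts must be non-negative")
        if not 0 <= self.prop_de <= 1 or not 0 <= self.prop_de_up_1 <= 1:
            raise ValueError("proportions must lie in [0, 1]")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def sizes_per_library(self) -> np.ndarray:
        n_libs = 2 * self.n_reps
        sizes = np.broadcast_to(
            np.asarray(self.library_sizes, dtype=float), (n_libs,)
        ).copy() if np.ndim(self.library_sizes) == 0 else np.asarray(
            self.library_sizes, dtype=float
        )
        if sizes.shape != (n_libs,):
            raise ValueError(f"library_sizes must be scalar or length {n_libs}")
        if (sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        return sizes


@dataclass(frozen=True)
class SimulatedExperiment:
    """Simulated counts plus complete ground truth.

    ``truth`` is a DataFrame indexed by gene with columns ``mu_1``, ``mu_2``
    (true expression per condition), ``is_de``, ``de_direction`` (1, 2 or 0)
    and ``unique_to`` (1, 2 or 0).  ``true_production_ratio`` is S_1/S_2 and
    ``true_factor = S_2/S_1`` is the normalization factor a perfect estimator
    would report for condition 1 against condition 2.
    """

    counts: CountMatrix
    truth: pd.DataFrame
    S_1: float
    S_2: float
    config: SimConfig = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def true_production_ratio(self) -> float:
        return self.S_1 / self.S_2

    @property
    def true_factor(self) -> float:
        return self.S_2 / self.S_1

    def libraries(self, condition: int) -> list[str]:
        prefix = f"cond{condition}_"
        return [lib for lib in self.counts.library_ids if lib.startswith(prefix)]

    def null_common_genes(self) -> list[str]:
        """Genes shared by both conditions and not DE (the truly null set)."""
        t = self.truth
        return list(t.index[(t["unique_to"] == 0) & ~t["is_de"]])


def build_source(
    counts: np.ndarray | None = None,
    log_mean: float = 4.0,
    log_sd: float = 2.0,
) -> Sampler:
    """Return a sampler of base expression values.

    With ``counts`` given, draws i.i.d. from its positive entries with
    replacement (at least 100 positive values required).  Otherwise draws
    ``max(round(exp(Normal(log_mean, log_sd))), 1)`` — a skewed, heavy-tailed
    stand-in for an empirical count distribution.
    """
    if counts is not None:
        positive = np.asarray(counts, dtype=float)
        positive = positive[positive > 0]
        if positive.size < 100:
            raise ValueError(
                f"empirical source needs >= 100 positive counts, got {positive.size}"
            )

        def sample_empirical(rng: np.random.Generator, size: int) -> np.ndarray:
            return rng.choice(positive, size=size, replace=True)

        return sample_empirical

    def sample_parametric(rng: np.random.Generator, size: int) -> np.ndarray:
        return np.maximum(np.rint(np.exp(rng.normal(log_mean, log_sd, size))), 1.0)

    return sample_parametric


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Draw one experiment: expression truths, then Poisson counts per library.

    Gene bookkeeping is deterministic given the config: the first
    ``floor(prop_de * n_common)`` common genes are DE, the first
    ``floor(prop_de_up_1 * n_de)`` of those are higher in condition 1
    (base expression values are i.i.d., so which indices carry the labels is
    immaterial); realized fractions are whatever the floors produce and are
    recorded in the truth table.  All randomness flows from ``config.seed``
    through spawned substreams (one for expression, one per library).
    """
    n_genes = config.n_common + config.n_unique_1 + config.n_unique_2
    if n_genes == 0:
        raise ValueError("no genes to simulate")
    n_libs = 2 * config.n_reps
    sizes = config.sizes_per_library()

    seq = np.random.SeedSequence(config.seed)
    expr_stream, *lib_streams = seq.spawn(1 + n_libs)
    rng = np.random.default_rng(expr_stream)

    source = build_source(config.empirical, config.log_mean, config.log_sd)
    base = source(rng, n_genes).astype(float)

    mu1 = base.copy()
    mu2 = base.copy()
    unique_to = np.zeros(n_genes, dtype=int)
    is_de = np.zeros(n_genes, dtype=bool)
    de_direction = np.zeros(n_genes, dtype=int)

    u1_start = config.n_common
    u2_start = config.n_common + config.n_unique_1
    mu2[u1_start:u2_start] = 0.0
    unique_to[u1_start:u2_start] = 1
    mu1[u2_start:] = 0.0
    unique_to[u2_start:] = 2

    n_de = int(np.floor(config.prop_de * config.n_common))
    n_up1 = int(np.floor(config.prop_de_up_1 * n_de))
    is_de[:n_de] = True
    de_direction[:n_up1] = 1
    de_direction[n_up1:n_de] = 2
    mu1[:n_up1] *= config.fold_change
    mu2[n_up1:n_de] *= config.fold_change

    s1 = float(mu1.sum())
    s2 = float(mu2.sum())
    if s1 <= 0 or s2 <= 0:
        raise ValueError("a condition has zero total expression")

    gene_ids = [f"g{i:06d}" for i in range(n_genes)]
    lib_ids = [f"cond{z}_rep{j + 1}" for z in (1, 2) for j in range(config.n_reps)]
    columns = []
    for idx, stream in enumerate(lib_streams):
        cond1 = idx < config.n_reps
        mu = mu1 if cond1 else mu2
        s = s1 if cond1 else s2
        lib_rng = np.random.default_rng(stream)
        columns.append(lib_rng.poisson(mu / s * sizes[idx]))
    counts = CountMatrix(
        gene_ids=tuple(gene_ids),
        library_ids=tuple(lib_ids),
        counts=np.column_stack(columns),
    )
    truth = pd.DataFrame(
        {
            "mu_1": mu1,
            "mu_2": mu2,
            "is_de": is_de,
            "de_direction": de_direction,
            "unique_to": unique_to,
        },
        index=gene_ids,
    )
    return SimulatedExperiment(counts=counts, truth=truth, S_1=s1, S_2=s2, config=config)


def true_factor(experiment: SimulatedExperiment, k: int, r: int) -> float:
    """Exact true production ratio S_k / S_r between two conditions."""
    outputs = {1: experiment.S_1, 2: experiment.S_2}
    if k not in outputs or r not in outputs:
        raise KeyError("conditions are 1 and 2")
    if outputs[r] == 0:
        raise ZeroDivisionError("reference condition has zero total output")
    return outputs[k] / outputs[r]
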