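"""Diagnostics: false-discovery curves, direction summaries, subset offsets,
and factor-recovery sweeps.

Everything here emits plain numeric tables (DataFrames) so the diagnostics
can be tested and consumed headlessly; rendering is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulation import SimConfig, SimulatedExperiment, simulate_experiment
from .tmm_core import MAStats, TrimParams, tmm_factor

__all__ = [
    "DirectionSummary",
    "SubsetOffset",
    "direction_summary",
    "false_discovery_curve",
    "recovery_sweep",
    "subset_offset",
]


@dataclass(frozen=True)
class DirectionSummary:
    """Counts of significant genes by direction at a fixed FDR threshold."""

    n_up_1: int
    n_up_2: int
    fdr_threshold: float

    @property
    def n_total(self) -> int:
        return self.n_up_1 + self.n_up_2

    @property
    def proportions(self) -> tuple[float, float] | None:
        """(prop higher in group 1, prop higher in group 2); None if nothing significant."""
        if self.n_total == 0:
            return None
        return self.n_up_1 / self.n_total, self.n_up_2 / self.n_total


@dataclass(frozen=True)
class SubsetOffset:
    """Median log-ratio of a gene subset plus a smoothed M distribution."""

    median_m: float
    n_genes: int
    density: pd.DataFrame  # columns: m, density
    bandwidth: float


def false_discovery_curve(
    ranking: Sequence[str],
    truth: SimulatedExperiment,
    restrict_common: bool = True,
) -> pd.DataFrame:
    """Cumulative count of truly-null genes as a function of rank.

    ``ranking`` is a gene list ordered from most to least significant.  With
    ``restrict_common`` (the default, matching how the simulation is scored),
    genes expressed in only one condition are dropped from the ranking before
    counting, so the curve reflects errors among genes that could actually be
    called either way.
    """
    t = truth.truth
    unknown = [g for g in ranking if g not in t.index]
    if unknown:
        raise KeyError(f"genes not in truth: {unknown[:3]}...")
    ranked = pd.Index(ranking)
    if restrict_common:
        common = set(t.index[t["unique_to"] == 0])
        ranked = pd.Index([g for g in ranked if g in common])
    is_null = ~t.loc[ranked, "is_de"].to_numpy()
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "gene_id": ranked,
            "false_discoveries": np.cumsum(is_null),
        }
    )


def direction_summary(de: pd.DataFrame, fdr_threshold: float) -> DirectionSummary:
    """Count significant genes higher in each group at ``fdr < threshold``."""
    if not 0 < fdr_threshold <= 1:
        raise ValueError("fdr_threshold must lie in (0, 1]")
    sig = de[de["fdr"] < fdr_threshold]
    return DirectionSummary(
        n_up_1=int((sig["direction"] == "up").sum()),
        n_up_2=int((sig["direction"] == "down").sum()),
        fdr_threshold=fdr_threshold,
    )


def subset_offset(
    ma: MAStats, subset: set[str], n_grid: int = 256
) -> SubsetOffset:
    """Median M of a gene subset (e.g. housekeeping genes) with a KDE table.

    A subset believed non-DE should center near the negated log2 factor; the
    median quantifies the offset, the Gaussian KDE (Scott bandwidth, a
    deterministic rule recorded in the result) gives the overlay curve.
    """
    members = np.fromiter(
        (g in subset for g in ma.gene_ids), dtype=bool, count=len(ma.gene_ids)
    )
    m = ma.M[members & ma.valid]
    if m.size == 0:
        raise ValueError("subset has no valid genes in this comparison")
    median = float(np.median(m))
    if m.size > 1 and np.ptp(m) > 0:
        kde = stats.gaussian_kde(m, bw_method="scott")
        bandwidth = float(np.sqrt(kde.covariance[0, 0]))
        span = 3 * bandwidth
        grid = np.linspace(m.min() - span, m.max() + span, n_grid)
        dens = kde(grid)
    else:  # degenerate subset: a single point mass, no smooth to draw
        bandwidth = 0.0
        grid = np.array([m[0]])
        dens = np.array([np.inf])
    return SubsetOffset(
        median_m=median,
        n_genes=int(m.size),
        density=pd.DataFrame({"m": grid, "density": dens}),
        bandwidth=bandwidth,
    )


def recovery_sweep(
    grid: Sequence[SimConfig], params: TrimParams = TrimParams()
) -> pd.DataFrame:
    """Simulate each config, estimate the factor, tabulate recovery error.

    One row per run: the true production ratio S_1/S_2, the TMM estimate
    (first condition-1 library against first condition-2 library), and the
    relative error.  Summary quantiles live in ``.attrs["rel_error_quantiles"]``.
    """
    if not grid:
        raise ValueError("empty config grid")
    rows = []
    for i, config in enumerate(grid):
        exp = simulate_experiment(config)
        k = exp.libraries(1)[0]
        r = exp.libraries(2)[0]
        res = tmm_factor(exp.counts, k, r, params)
        true_ratio = exp.true_production_ratio
        rows.append(
            {
                "run": i,
                "n_genes": exp.counts.n_genes,
                "true_production_ratio": true_ratio,
                "estimated_production_ratio": res.production_ratio,
                "rel_error": abs(res.production_ratio - true_ratio) / true_ratio,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["rel_error_quantiles"] = (
        table["rel_error"].quantile([0.5, 0.9, 0.95]).to_dict()
    )
    return table
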