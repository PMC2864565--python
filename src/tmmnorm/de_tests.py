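"""Count-based differential-expression tests on effective library sizes.

Three tests, all consuming the effective (normalization-adjusted) library
sizes from :mod:`tmmnorm.tmm_core`:

* :func:`exact_binomial_test` — the SAGE-style conditional exact test: given
  the total ``t = y1 + y2`` for one gene, ``y1`` is Binomial(t, n1/(n1+n2))
  under the null of equal expression, and the two-sided p-value sums the
  probabilities of all outcomes no more likely than the observed one.
* :func:`poisson_lr_test` — per-gene Poisson likelihood-ratio test with the
  (log) effective library size as offset; closed-form MLEs, chi-squared(1)
  reference.
* :func:`poisson_exact_test` — pools counts within each replicated group
  (group totals of Poissons are Poisson) and applies the conditional exact
  test to the pooled counts and pooled effective sizes.

Results come back as a :class:`pandas.DataFrame` (the "DE table") indexed by
gene with columns ``p_value``, ``fdr`` (Benjamini-Hochberg), ``log2_fc``
(group 1 over group 2, on effective-size-normalized proportions), ``direction``
and ``statistic``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .count_io import CountMatrix
from .tmm_core import TMMResult, effective_sizes_two_sample

__all__ = [
    "GroupDesign",
    "bh_adjust",
    "exact_binomial_test",
    "poisson_exact_test",
    "poisson_lr_test",
    "two_library_test",
]

# relative slack when comparing outcome probabilities to the observed one,
# so floating-point-equal probabilities (e.g. symmetric outcomes) are included
_TIE_SLACK = 1e-7


@dataclass(frozen=True)
class GroupDesign:
    """Two-group design: library -> group label, plus effective sizes.

    ``effective_sizes`` are the normalization-adjusted library sizes
    (``N_k * factor_k``); they enter every test as the exposure.
    """

    groups: Mapping[str, str]
    effective_sizes: Mapping[str, float]

    def __post_init__(self) -> None:
        labels = sorted(set(self.groups.values()))
        if len(labels) != 2:
            raise ValueError(f"exactly two group labels required, got {labels}")
        for lib, size in self.effective_sizes.items():
            if size <= 0:
                raise ValueError(f"effective size for {lib!r} must be positive")
        missing = set(self.groups) - set(self.effective_sizes)
        if missing:
            raise ValueError(f"no effective size for libraries {sorted(missing)}")
        object.__setattr__(self, "_labels", tuple(labels))

    @property
    def labels(self) -> tuple[str, str]:
        return self._labels  # type: ignore[attr-defined]

    def libraries(self, label: str) -> list[str]:
        return [lib for lib, g in self.groups.items() if g == label]


def exact_binomial_test(y1: int, y2: int, n1: float, n2: float) -> float:
    """Two-sided conditional exact p-value for one gene's pair of counts.

    Conditional on ``t = y1 + y2``, ``y1 ~ Binomial(t, n1/(n1+n2))`` under
    the null.  The two-sided p-value sums P(X = x) over every outcome whose
    probability does not exceed the observed one (minimum-likelihood method,
    with a tiny relative slack for floating-point ties).  Both counts zero
    returns 1.
    """
    if y1 < 0 or y2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("effective sizes must be positive")
    t = int(y1) + int(y2)
    if t == 0:
        return 1.0
    prob = n1 / (n1 + n2)
    pmf = stats.binom.pmf(np.arange(t + 1), t, prob)
    cutoff = pmf[int(y1)] * (1 + _TIE_SLACK)
    if cutoff >= pmf.max():  # observed at the mode: every outcome counts
        return 1.0
    return min(float(pmf[pmf <= cutoff].sum()), 1.0)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log2_fc(y1: np.ndarray, y2: np.ndarray, n1: float, n2: float) -> np.ndarray:
    """Log2 fold-change of normalized proportions, half-count offset for zeros.

    The continuity offset is used for display only; p-values never see it.
    """
    y1 = y1.astype(float)
    y2 = y2.astype(float)
    needs_offset = (y1 == 0) | (y2 == 0)
    a1 = np.where(needs_offset, y1 + 0.5, y1)
    a2 = np.where(needs_offset, y2 + 0.5, y2)
    return np.log2(a1 / n1) - np.log2(a2 / n2)


def _assemble(
    gene_ids: tuple,
    p: np.ndarray,
    log2_fc: np.ndarray,
    statistic: np.ndarray,
) -> pd.DataFrame:
    direction = np.where(log2_fc > 0, "up", np.where(log2_fc < 0, "down", "none"))
    return pd.DataFrame(
        {
            "p_value": p,
            "fdr": bh_adjust(p),
            "log2_fc": log2_fc,
            "direction": direction,
            "statistic": statistic,
        },
        index=list(gene_ids),
    )


def two_library_test(
    counts: CountMatrix, k: str, r: str, norm: TMMResult | None = None
) -> pd.DataFrame:
    """Exact test of each gene between two single libraries.

    With ``norm`` given, both library sizes are adjusted by the square root
    of the TMM factor (multiplying k's, dividing r's) before testing;
    otherwise the raw sizes are used.  Group 1 is library ``k``.
    """
    y1 = counts.column(k)
    y2 = counts.column(r)
    n1 = float(counts.library_size(k))
    n2 = float(counts.library_size(r))
    if norm is not None:
        n1, n2 = effective_sizes_two_sample(n1, n2, norm.factor)
    p = np.array([exact_binomial_test(a, b, n1, n2) for a, b in zip(y1, y2)])
    lfc = _log2_fc(y1, y2, n1, n2)
    return _assemble(counts.gene_ids, p, lfc, lfc)


def _group_arrays(
    counts: CountMatrix, design: GroupDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-library counts (genes x libs), effective sizes, and group-1 mask."""
    libs = [lib for lib in counts.library_ids if lib in design.groups]
    if not libs:
        raise ValueError("design refers to no library of the count matrix")
    y = np.column_stack([counts.column(lib) for lib in libs]).astype(float)
    sizes = np.array([design.effective_sizes[lib] for lib in libs], dtype=float)
    in_g1 = np.array([design.groups[lib] == design.labels[0] for lib in libs])
    if not in_g1.any() or in_g1.all():
        raise ValueError("each group needs at least one library")
    return y, sizes, in_g1


def poisson_lr_test(counts: CountMatrix, design: GroupDesign) -> pd.DataFrame:
    """Poisson likelihood-ratio test per gene, effective sizes as offsets.

    Model: ``Y_gk ~ Poisson(lambda_{g,z(k)} * Ntilde_k)``.  The MLEs are
    closed-form rate fractions (group total counts over group total effective
    sizes); the LR statistic ``2 * sum_k Y_gk * ln(lambda_hat_{z(k)} /
    lambda_hat_0)`` is referred to chi-squared with 1 degree of freedom.
    """
    y, sizes, in_g1 = _group_arrays(counts, design)
    s1, s2 = float(sizes[in_g1].sum()), float(sizes[~in_g1].sum())
    t1 = y[:, in_g1].sum(axis=1)
    t2 = y[:, ~in_g1].sum(axis=1)
    lam1 = t1 / s1
    lam2 = t2 / s2
    lam0 = (t1 + t2) / (s1 + s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        # 0 * ln(0) := 0 — a group with zero counts contributes nothing
        term1 = np.where(t1 > 0, t1 * np.log(np.where(t1 > 0, lam1, 1) / np.where(lam0 > 0, lam0, 1)), 0.0)
        term2 = np.where(t2 > 0, t2 * np.log(np.where(t2 > 0, lam2, 1) / np.where(lam0 > 0, lam0, 1)), 0.0)
    lr = 2.0 * (term1 + term2)
    lr = np.maximum(lr, 0.0)  # guard roundoff on proportional counts
    p = stats.chi2.sf(lr, df=1)
    p = np.where(lr == 0, 1.0, p)
    lfc = _log2_fc(t1, t2, s1, s2)
    return _assemble(counts.gene_ids, p, lfc, lr)


def poisson_exact_test(counts: CountMatrix, design: GroupDesign) -> pd.DataFrame:
    """Exact Poisson test for two replicated groups.

    Group totals of independent Poisson counts are Poisson, so conditioning
    on the overall total reduces to the binomial exact test on the pooled
    counts with pooled effective sizes as the exposure split.
    """
    y, sizes, in_g1 = _group_arrays(counts, design)
    s1, s2 = float(sizes[in_g1].sum()), float(sizes[~in_g1].sum())
    t1 = y[:, in_g1].sum(axis=1).astype(int)
    t2 = y[:, ~in_g1].sum(axis=1).astype(int)
    p = np.array([exact_binomial_test(a, b, s1, s2) for a, b in zip(t1, t2)])
    lfc = _log2_fc(t1, t2, s1, s2)
    return _assemble(counts.gene_ids, p, lfc, lfc)
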