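"""Trimmed mean of M-values (TMM) normalization.

RNA-seq read counts measure *proportions*, not absolute expression: each
library spreads its ``N_k`` reads over whatever RNA the sample produced.  If
one sample has a larger total RNA output ``S_k`` (for example because a set
of genes is expressed only there), every shared gene receives proportionally
fewer reads, and naive library-size scaling mistakes that global shift for
differential expression — composition bias.

TMM estimates the relative RNA production ``f = S_k / S_r`` of two libraries
from the counts alone, assuming most genes are not differentially expressed.
For each gene expressed in both libraries it forms

    M_g = log2( (Y_gk / N_k) / (Y_gr / N_r) )      (log-fold-change)
    A_g = 0.5 * log2( (Y_gk / N_k) * (Y_gr / N_r) ) (average log abundance)

removes a fixed fraction of genes from each tail of both the M and the A
distribution (the double trim; defaults 30% of M, 5% of A per tail), and
averages the surviving M values with precision weights

    w_g = 1 / var(M_g),
    var(M_g) ~= (N_k - Y_gk)/(N_k * Y_gk) + (N_r - Y_gr)/(N_r * Y_gr)

the delta-method (binomial) variance of a log relative risk.  The resulting
``log2_factor`` exponentiates to the normalization factor multiplying
library k's size; ``2**(-log2_factor)`` estimates the production ratio
``S_k / S_r``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .count_io import CountMatrix

__all__ = [
    "MAStats",
    "NormFactors",
    "TMMError",
    "TMMResult",
    "TrimParams",
    "compute_ma",
    "doubly_trim",
    "effective_sizes_two_sample",
    "tmm_factor",
    "tmm_factors",
]


class TMMError(ValueError):
    """Raised when a TMM factor cannot be computed (e.g. empty trim set)."""


@dataclass(frozen=True)
class TrimParams:
    """Trim fractions and options for the doubly trimmed mean.

    ``m_trim`` and ``a_trim`` are the fractions removed from *each* tail of
    the M and A distributions (defaults 0.30 and 0.05).  ``a_min`` optionally
    drops genes with average log abundance below a floor before trimming.
    ``weighted`` selects the precision-weighted mean (default) over the plain
    trimmed mean.
    """

    m_trim: float = 0.30
    a_trim: float = 0.05
    a_min: float | None = None
    weighted: bool = True

    def __post_init__(self) -> None:
        for name, value in (("m_trim", self.m_trim), ("a_trim", self.a_trim)):
            if not 0.0 <= value < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5), got {value}")


@dataclass(frozen=True)
class MAStats:
    """Per-gene M, A, delta-method variance and weight for one library pair.

    Entries are aligned with ``gene_ids``.  ``valid`` is False exactly where
    M is undefined (a zero count in either library); invalid entries carry
    NaN.  Genes whose count equals the full library size in both libraries
    have zero delta-method variance; they are flagged invalid with a warning
    since their weight would be infinite.
    """

    gene_ids: tuple
    M: np.ndarray
    A: np.ndarray
    var_M: np.ndarray
    weight: np.ndarray
    valid: np.ndarray
    sample_id: str
    reference_id: str

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass(frozen=True)
class TMMResult:
    """A pairwise TMM estimate: library ``sample_id`` against ``reference_id``.

    ``factor`` multiplies the sample library size to give its effective size;
    ``production_ratio = 1/factor`` estimates the relative total RNA output
    S_sample / S_reference.
    """

    log2_factor: float
    factor: float
    production_ratio: float
    kept_genes: tuple
    n_zero_removed: int
    n_trimmed: int
    sample_id: str
    reference_id: str
    params: TrimParams


@dataclass(frozen=True)
class NormFactors:
    """Per-library TMM factors and effective library sizes vs one reference."""

    library_ids: tuple
    factors: np.ndarray
    effective_sizes: np.ndarray
    reference_id: str
    results: tuple = field(repr=False, default=())

    def factor(self, library_id: str) -> float:
        return float(self.factors[self.library_ids.index(str(library_id))])

    def effective_size(self, library_id: str) -> float:
        return float(self.effective_sizes[self.library_ids.index(str(library_id))])

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.library_ids, map(float, self.effective_sizes)))


def compute_ma(counts: CountMatrix, k: str, r: str) -> MAStats:
    """Gene-wise M (log2 ratio), A (mean log2 abundance) and weights for k vs r.

    Genes with a zero count in either library are flagged invalid — their
    log-fold-change is undefined and they are removed ahead of the trimmed
    mean.
    """
    yk = counts.column(k).astype(float)
    yr = counts.column(r).astype(float)
    nk = float(counts.library_size(k))
    nr = float(counts.library_size(r))
    if nk <= 0 or nr <= 0:
        raise TMMError("library sizes must be positive")

    valid = (yk > 0) & (yr > 0)
    M = np.full(counts.n_genes, np.nan)
    A = np.full(counts.n_genes, np.nan)
    var_M = np.full(counts.n_genes, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        # M and A are computed from exact integer cross-products so that
        # (a) swapping k and r negates M bitwise (the larger product is put
        # in the numerator, so both orientations take the log of the same
        # quotient), and (b) uniformly scaling one library's counts cancels
        # exactly in the quotient.  This keeps the trim's rank order — and
        # hence the kept gene set — identical across those transformations.
        num = yk[valid] * nr
        den = yr[valid] * nk
        M[valid] = np.where(num >= den, np.log2(num / den), -np.log2(den / num))
        A[valid] = 0.5 * np.log2((yk[valid] * yr[valid]) / (nk * nr))
        var_M[valid] = (nk - yk[valid]) / (nk * yk[valid]) + (nr - yr[valid]) / (
            nr * yr[valid]
        )

    degenerate = valid & (var_M == 0)
    if degenerate.any():
        warnings.warn(
            "excluding gene(s) with count equal to library size in both "
            "libraries (zero delta-method variance)",
            stacklevel=2,
        )
        valid = valid & ~degenerate
        M[degenerate] = A[degenerate] = var_M[degenerate] = np.nan

    weight = np.full(counts.n_genes, np.nan)
    with np.errstate(divide="ignore"):
        weight[valid] = 1.0 / var_M[valid]
    return MAStats(
        gene_ids=counts.gene_ids,
        M=M,
        A=A,
        var_M=var_M,
        weight=weight,
        valid=valid,
        sample_id=str(k),
        reference_id=str(r),
    )


def _midranks(values: np.ndarray) -> np.ndarray:
    """1-based midranks: tied values share the average of their ranks.

    Midranks are exactly antisymmetric under negation
    (``rank(-x) = n + 1 - rank(x)``), so the trim keeps or removes a tie
    group wholesale and the k-vs-r / r-vs-k factors negate exactly.
    """
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    ranks[order] = np.arange(1, len(values) + 1)
    # average ranks within tie groups
    sorted_vals = values[order]
    boundaries = np.concatenate(([0], np.nonzero(np.diff(sorted_vals))[0] + 1, [len(values)]))
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        if hi - lo > 1:
            ranks[order[lo:hi]] = (lo + 1 + hi) / 2.0
    return ranks


def doubly_trim(ma: MAStats, params: TrimParams = TrimParams()) -> np.ndarray:
    """Apply the double trim; return the kept gene ids (the set G*).

    Candidates are the valid genes (optionally with ``A >= a_min``).  With
    ``n`` candidates, a gene is kept when its M-rank lies in
    ``[floor(n*m_trim)+1, n - floor(n*m_trim)]`` and its A-rank lies in the
    analogous A interval — the intersection of the two per-statistic
    keep-sets over the same candidate pool.
    """
    candidates = ma.valid.copy()
    if params.a_min is not None:
        candidates &= ma.A >= params.a_min
    n = int(candidates.sum())
    if n == 0:
        raise TMMError(
            "no valid genes enter the trim; lower a_min or check the counts"
        )
    m = ma.M[candidates]
    a = ma.A[candidates]
    lo_m = math.floor(n * params.m_trim) + 1
    hi_m = n - math.floor(n * params.m_trim)
    lo_a = math.floor(n * params.a_trim) + 1
    hi_a = n - math.floor(n * params.a_trim)
    rank_m = _midranks(m)
    rank_a = _midranks(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        raise TMMError(
            "double trim removed every gene; use smaller m_trim/a_trim fractions"
        )
    ids = np.asarray(ma.gene_ids, dtype=object)[candidates]
    return ids[keep]


def tmm_factor(
    counts: CountMatrix, k: str, r: str, params: TrimParams = TrimParams()
) -> TMMResult:
    """Pairwise TMM normalization factor for library ``k`` against reference ``r``.

    ``log2_factor`` is the precision-weighted mean of M over the doubly
    trimmed gene set G* (unweighted mean if ``params.weighted`` is False).
    """
    ma = compute_ma(counts, k, r)
    if ma.n_valid == 0:
        raise TMMError(f"no gene has positive counts in both {k!r} and {r!r}")
    kept = doubly_trim(ma, params)
    kept_set = set(kept)
    mask = np.fromiter((g in kept_set for g in ma.gene_ids), bool, len(ma.gene_ids))
    m = ma.M[mask]
    if params.weighted:
        w = ma.weight[mask]
        log2_factor = float(np.sum(w * m) / np.sum(w))
    else:
        log2_factor = float(np.mean(m))
    return TMMResult(
        log2_factor=log2_factor,
        factor=float(2.0 ** log2_factor),
        production_ratio=float(2.0 ** (-log2_factor)),
        kept_genes=tuple(kept),
        n_zero_removed=int((~ma.valid).sum()),
        n_trimmed=int(ma.n_valid - len(kept)),
        sample_id=str(k),
        reference_id=str(r),
        params=params,
    )


def _auto_reference(counts: CountMatrix, params: TrimParams) -> str:
    """Pick the library whose median A against the first library is closest to 0.

    A is an average log2 proportion (negative for realistic depths), so this
    favours the library with the most abundant typical gene — a deterministic
    stand-in for "most representative"; ties go to the earlier library.
    """
    first = counts.library_ids[0]
    best, best_score = first, math.inf
    for lib in counts.library_ids:
        ma = compute_ma(counts, lib, first)
        if ma.n_valid == 0:
            continue
        score = abs(float(np.nanmedian(ma.A[ma.valid])))
        if score < best_score:
            best, best_score = lib, score
    return best


def tmm_factors(
    counts: CountMatrix,
    reference: str = "auto",
    params: TrimParams = TrimParams(),
) -> NormFactors:
    """TMM factors for every library against one reference.

    The reference keeps factor 1; every other library's factor is its
    pairwise TMM factor against the reference.  ``reference="auto"`` selects
    the library whose median log-ratio against the first library is closest
    to zero (the most "typical" library); factors are not recentred to
    multiply to 1.
    """
    if counts.n_libraries < 2:
        raise TMMError("need at least two libraries")
    ref = _auto_reference(counts, params) if reference == "auto" else str(reference)
    if ref not in counts.library_ids:
        raise KeyError(f"unknown reference library {ref!r}")
    factors = np.ones(counts.n_libraries)
    results = []
    for i, lib in enumerate(counts.library_ids):
        if lib == ref:
            continue
        try:
            res = tmm_factor(counts, lib, ref, params)
        except TMMError as exc:
            raise TMMError(f"TMM failed for pair ({lib!r}, {ref!r}): {exc}") from exc
        factors[i] = res.factor
        results.append(res)
    effective = counts.library_sizes * factors
    return NormFactors(
        library_ids=counts.library_ids,
        factors=factors,
        effective_sizes=effective,
        reference_id=ref,
        results=tuple(results),
    )


def effective_sizes_two_sample(
    n_k: float, n_r: float, factor: float
) -> tuple[float, float]:
    """Split a pairwise factor symmetrically over both library sizes.

    Returns ``(N_k * sqrt(f), N_r / sqrt(f))`` so the ratio of adjusted
    sizes is ``(N_k / N_r) * f`` while their product is preserved — the
    adjustment used when a two-library exact test consumes the factor.
    """
    if n_k <= 0 or n_r <= 0 or factor <= 0:
        raise TMMError("library sizes and factor must be positive")
    root = math.sqrt(factor)
    return n_k * root, n_r / root
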