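"""Renyi/Hill diversity, Shannon entropy, Pielou evenness, slope diagnostics.

Renyi entropy of order ``alpha`` generalizes Shannon entropy over a
clonotype frequency vector p:

    H_a = ln(sum_i p_i^a) / (1 - a)      a >= 0, a != 1
    H_1 = -sum_i p_i ln p_i              (Shannon, the a -> 1 limit)
    H_0 = ln S                           (S = richness)
    H_inf = -ln max_i p_i                (clonal dominance)

The exponential exp(H_a) is the Hill diversity: an *effective number of
clonotypes*, directly comparable across orders. Sweeping ``alpha`` from 0
upward traces a diversity profile that starts at the richness and decays
toward the reciprocal of the top clonotype frequency; how fast it decays
reflects how uneven the repertoire is. Natural logarithms are used
throughout, so Hill numbers are in units of clonotypes.

All functions accept either raw counts or normalized frequencies; vectors
are renormalized internally (entropies are scale-free in this sense).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .repio import ClonotypeTable

__all__ = [
    "DEFAULT_ALPHAS",
    "DiversityProfile",
    "as_frequencies",
    "shannon_entropy",
    "renyi_entropy",
    "diversity_profile",
    "pielou_evenness",
    "steepest_descent_slope",
]

#: Default Renyi-order grid: dense near the informative 0..1 range, then
#: doubling until the profile has stabilized, closing at the dominance limit.
DEFAULT_ALPHAS: tuple[float, ...] = (
    0.0, 0.25, 0.5, 0.75, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, np.inf,
)


def as_frequencies(p) -> np.ndarray:
    """Validate and normalize a count/frequency vector to frequencies."""
    if isinstance(p, ClonotypeTable):
        p = p.counts
    arr = np.asarray(p, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("frequencies/counts must be positive and finite")
    total = arr.sum()
    if abs(total - 1.0) > 1e-9:
        arr = arr / total
    return arr


def shannon_entropy(p) -> float:
    """Shannon entropy H = -sum p_i ln p_i, in nats."""
    freq = as_frequencies(p)
    return float(-(freq * np.log(freq)).sum())


def renyi_entropy(p, alpha: float) -> float:
    """Renyi entropy of order *alpha* (>= 0, may be inf), in nats."""
    if alpha < 0:
        raise ValueError(f"Renyi order must be >= 0, got {alpha}")
    freq = as_frequencies(p)
    if alpha == 0:
        return float(np.log(freq.size))
    if alpha == 1:
        return float(-(freq * np.log(freq)).sum())
    if np.isinf(alpha):
        return float(-np.log(freq.max()))
    # log-sum-exp of alpha*ln(p) for numerical stability at large alpha
    log_p = np.log(freq)
    m = (alpha * log_p).max()
    log_sum = m + np.log(np.exp(alpha * log_p - m).sum())
    return float(log_sum / (1.0 - alpha))


@dataclass(frozen=True)
class DiversityProfile:
    """Hill diversities (effective clonotype numbers) over a grid of orders."""

    alphas: tuple[float, ...]
    renyi: tuple[float, ...]
    hill: tuple[float, ...]

    def __post_init__(self) -> None:
        hill = np.asarray(self.hill)
        if np.any(np.diff(hill) > 1e-9 * np.maximum(hill[:-1], 1.0)):
            raise ValueError("Hill diversity must be non-increasing in alpha")


def diversity_profile(p, alphas=DEFAULT_ALPHAS) -> DiversityProfile:
    """Diversity profile: Hill number exp(H_alpha) along an alpha grid."""
    alphas = tuple(float(a) for a in alphas)
    if any(b <= a for a, b in zip(alphas, alphas[1:])):
        raise ValueError("alpha grid must be strictly ascending")
    freq = as_frequencies(p)
    renyi = tuple(renyi_entropy(freq, a) for a in alphas)
    hill = tuple(float(np.exp(h)) for h in renyi)
    return DiversityProfile(alphas=alphas, renyi=renyi, hill=hill)


def pielou_evenness(p) -> float:
    """Pielou evenness J = H / ln(S), in [0, 1]; requires richness >= 2."""
    freq = as_frequencies(p)
    if freq.size < 2:
        raise ValueError("Pielou evenness is undefined for a single clonotype")
    return shannon_entropy(freq) / float(np.log(freq.size))


def steepest_descent_slope(table, min_span: float = 0.25) -> float:
    """Steepest log-log slope of the rank-abundance curve.

    Counts are ranked descending and runs of tied counts are collapsed to
    a single point at their midpoint rank. The returned value is the most
    negative chord slope of log10(count) versus log10(rank) between pairs
    of collapsed points at least *min_span* decades of rank apart (no
    curve fitting). The minimum-span chord suppresses the count
    quantization jitter that makes pointwise differences unstable, and the
    final plateau is excluded as a chord endpoint because it is
    right-censored by the finite richness. A perfectly even table has
    slope 0.
    """
    counts = table.counts if isinstance(table, ClonotypeTable) else np.asarray(table)
    counts = np.sort(np.asarray(counts, dtype=float))[::-1]
    if counts.size < 3:
        raise ValueError("need at least 3 clonotypes for a slope estimate")
    values, starts, run_lengths = np.unique(-counts, return_index=True, return_counts=True)
    plateau_counts = -values  # ascending unique of negated => descending counts
    midpoint_ranks = starts + (run_lengths + 1) / 2.0  # 1-based midpoint rank
    if plateau_counts.size == 1:
        return 0.0
    x = np.log10(midpoint_ranks)
    y = np.log10(plateau_counts)
    # last plateau is right-censored unless the curve is just two points
    last = len(x) - 1 if len(x) > 2 else len(x)
    j = np.searchsorted(x, x + min_span)
    valid = j < last
    if not valid.any():
        # short curve: fall back to consecutive-point differences
        xx, yy = (x[:last], y[:last]) if last < len(x) and last >= 2 else (x, y)
        return float(np.min(np.diff(yy) / np.diff(xx)))
    i = np.flatnonzero(valid)
    j = j[valid]
    return float(np.min((y[j] - y[i]) / (x[j] - x[i])))
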