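"""Shannon-entropy filtering of scarce uninformative clonotypes (SUC).

Over-sequencing a small sample inflates the observed clonotype list with
low-abundance artifacts. The exponential of the Shannon entropy of the
clonotype frequencies — the effective clonotype number — is used as an
objective cutoff: only the ``round(exp(H))`` most abundant clonotypes are
kept, the remainder being discarded as SUC. The entropy is computed once
on the input table (no recomputation after filtering).

Boundary ties (several clonotypes sharing the cutoff count) are resolved
by the package-wide canonical sort (count descending, then lexicographic
key), so the kept richness equals the effective number exactly and the
result is reproducible byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .diversity import shannon_entropy
from .repio import ClonotypeTable

__all__ = ["FilterResult", "effective_clonotype_number", "shannon_filter", "min_count_filter"]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class FilterResult:
    """Partition of a table into kept clonotypes and discarded SUC."""

    kept: ClonotypeTable
    suc: ClonotypeTable
    n_effective: int
    entropy: float  # Shannon entropy of the input table, nats


def effective_clonotype_number(table: ClonotypeTable) -> int:
    """Effective clonotype number round(exp(H)) of a table, in clonotypes.

    Rounding is half-away-from-zero; the result is clipped to
    ``[1, richness]`` (exp(H) never exceeds richness mathematically, but
    rounding could nudge it past at near-perfect evenness).
    """
    if table.richness == 0:
        raise ValueError("effective clonotype number of an empty table")
    n = _round_half_away(math.exp(shannon_entropy(table.counts)))
    return max(1, min(n, table.richness))


def shannon_filter(table: ClonotypeTable) -> FilterResult:
    """Keep the exp(Shannon) most abundant clonotypes; discard the rest as SUC."""
    if table.richness == 0:
        raise ValueError("cannot filter an empty table")
    entropy = shannon_entropy(table.counts)
    n_eff = effective_clonotype_number(table)
    return FilterResult(
        kept=table.head_table(n_eff),
        suc=table.tail_table(n_eff),
        n_effective=n_eff,
        entropy=entropy,
    )


def min_count_filter(table: ClonotypeTable, min_count: int = 2) -> ClonotypeTable:
    """Baseline filter: drop clonotypes below *min_count* (e.g. singletons)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = table.df[table.df["count"] >= min_count]
    return ClonotypeTable(kept, sample_id=table.sample_id, validate=False)
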