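"""Rarefaction, Morisita-Horn similarity, overlap and coverage statistics.

Rarefaction draws a fixed number of sequences *without replacement* from a
clonotype count vector (multivariate hypergeometric sampling); it is the
normalization used to compare repertoires sequenced at different depths.
Requesting a depth at or beyond the table total returns the table
unchanged (with a warning) — the whole dataset is the only possible
subsample.

The Morisita-Horn index quantifies abundance-weighted similarity between
two repertoires on a common key set:

    MH = 2 sum(x_i y_i) / [(sum x_i^2 / X^2 + sum y_i^2 / Y^2) X Y]

with X = sum x_i, Y = sum y_i. It is symmetric, lies in [0, 1] and is
invariant to rescaling either vector.

Replicate-overlap tools label each clonotype of a union by the number of
replicates containing it (private / shared-by-two / shared-by-three ...),
build per-replicate sharing-enrichment curves down the abundance ranking,
and measure cumulative richness coverage of a reference repertoire by
accumulating subsamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repio import ClonotypeTable

__all__ = [
    "rarefy",
    "rarefy_counts",
    "morisita_horn",
    "morisita_horn_tables",
    "pearson",
    "align_tables",
    "SharingDecomposition",
    "overlap_decomposition",
    "sharing_spectrum",
    "richness_coverage",
]


def rarefy_counts(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Rarefy an integer count vector to *depth* tokens without replacement."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if depth >= total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy(
    table: ClonotypeTable, depth: int, rng: np.random.Generator
) -> ClonotypeTable:
    """Randomly rarefy a table to *depth* sequences without replacement.

    If *depth* is at or above the table total, the input table is returned
    unchanged (with a warning).
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    if depth >= table.total:
        warnings.warn(
            f"rarefaction depth {depth} >= table total {table.total}; "
            f"returning the table unchanged",
            stacklevel=2,
        )
        return table
    sub = rng.multivariate_hypergeometric(table.counts, depth)
    keep = sub > 0
    df = table.df.loc[keep, ["v_gene", "cdr3_aa", "j_gene"]].copy()
    df["count"] = sub[keep]
    return ClonotypeTable(df, sample_id=table.sample_id, validate=False)


def morisita_horn(x, y) -> float:
    """Morisita-Horn similarity between two aligned abundance vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("abundance vectors must be aligned to the same key set")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        raise ValueError("zero-total abundance vector")
    num = 2.0 * float(x @ y)
    den = (float(x @ x) / X**2 + float(y @ y) / Y**2) * X * Y
    return num / den


def align_tables(tables: Sequence[ClonotypeTable]) -> pd.DataFrame:
    """Align tables on the union key set.

    Returns a DataFrame indexed by 'v|cdr3|j' key strings with one integer
    count column per table (zeros for absent clonotypes), ordered by the
    canonical sort of the summed counts.
    """
    if not tables:
        raise ValueError("no tables to align")
    cols = {}
    for i, t in enumerate(tables):
        if t.richness == 0:
            raise ValueError("cannot align an empty table")
        name = t.sample_id or f"table_{i}"
        if name in cols:
            name = f"{name}_{i}"
        cols[name] = pd.Series(t.counts, index=t.key_strings())
    aligned = pd.DataFrame(cols).fillna(0).astype(np.int64)
    order = (-aligned.sum(axis=1)).argsort(kind="mergesort")
    return aligned.iloc[order]


def morisita_horn_tables(a: ClonotypeTable, b: ClonotypeTable) -> float:
    """Morisita-Horn similarity of two tables aligned on their union keys."""
    aligned = align_tables([a, b])
    return morisita_horn(aligned.iloc[:, 0], aligned.iloc[:, 1])


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two paired vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class SharingDecomposition:
    """Union clonotypes of k replicates labeled by sharing multiplicity.

    ``counts[m]`` is the number of union clonotypes present in exactly
    ``m`` replicates (m = 1..k); ``percentages`` are the same as a
    percentage of the union richness. ``cumulative_frequency_shared_all``
    gives, per replicate, the fraction of its sequences carried by the
    fully shared clonotype set.
    """

    counts: dict[int, int]
    percentages: dict[int, float]
    union_richness: int
    cumulative_frequency_shared_all: tuple[float, ...]

    @property
    def private(self) -> int:
        return self.counts.get(1, 0)

    @property
    def shared_by_two(self) -> int:
        return self.counts.get(2, 0)

    @property
    def shared_by_three(self) -> int:
        return self.counts.get(3, 0)


def _presence_matrix(tables: Sequence[ClonotypeTable]) -> pd.DataFrame:
    aligned = align_tables(tables)
    return aligned


def overlap_decomposition(tables: Sequence[ClonotypeTable]) -> SharingDecomposition:
    """Decompose the union of k >= 2 replicates by sharing multiplicity."""
    if len(tables) < 2:
        raise ValueError("need at least 2 tables")
    aligned = align_tables(tables)
    presence = (aligned.to_numpy() > 0)
    multiplicity = presence.sum(axis=1)
    k = len(tables)
    union = len(aligned)
    counts = {m: int((multiplicity == m).sum()) for m in range(1, k + 1)}
    percentages = {m: 100.0 * c / union for m, c in counts.items()}
    shared_all = multiplicity == k
    cum_freq = tuple(
        float(aligned.iloc[:, i].to_numpy()[shared_all].sum() / aligned.iloc[:, i].sum())
        for i in range(k)
    )
    return SharingDecomposition(
        counts=counts,
        percentages=percentages,
        union_richness=union,
        cumulative_frequency_shared_all=cum_freq,
    )


def sharing_spectrum(tables: Sequence[ClonotypeTable]) -> list[pd.DataFrame]:
    """Per-replicate sharing-enrichment curves down the abundance ranking.

    For each table, clonotypes are walked in canonical (most- to
    least-abundant) order; the cumulative count of each sharing group
    (multiplicity 1..k) is incremented whenever a clonotype of that group
    is encountered. Final curve values sum to the table's richness.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables")
    aligned = align_tables(tables)
    presence = aligned.to_numpy() > 0
    multiplicity = pd.Series(presence.sum(axis=1), index=aligned.index)
    k = len(tables)
    curves = []
    for table in tables:
        keys = table.key_strings()  # canonical order already
        mult = multiplicity.loc[keys].to_numpy()
        df = pd.DataFrame({"rank": np.arange(1, len(keys) + 1)})
        for m in range(1, k + 1):
            df[f"shared_by_{m}"] = np.cumsum(mult == m)
        curves.append(df)
    return curves


def richness_coverage(
    subsamples: Sequence[ClonotypeTable], reference_richness: int
) -> np.ndarray:
    """Cumulative richness coverage of a reference by k = 1..n subsamples.

    ``coverage[k-1]`` is the fraction of the reference richness present in
    the union of the first k subsample key sets; non-decreasing in k.
    """
    if reference_richness < 1:
        raise ValueError("reference_richness must be >= 1")
    seen: set[str] = set()
    coverage = np.empty(len(subsamples))
    for i, sub in enumerate(subsamples):
        seen.update(sub.key_strings())
        coverage[i] = len(seen) / reference_richness
    return coverage
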