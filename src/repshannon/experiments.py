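"""Subsampling experiment battery: representativeness, reproducibility,
replicate sharing, and richness coverage.

Each experiment rarefies a reference dataset to a grid of depths
(default 500 to 1*10^6 sequences), repeats the draw ``n_iter`` times
(default 100) and summarizes the resulting ensembles by their median and
a 95% percentile interval (2.5th-97.5th). Depths at or above the dataset
total return the full dataset, so those grid points are exact.

All randomness flows from a single integer seed through a spawned
``SeedSequence`` tree, one child stream per (depth, iteration): results
are reproducible bit-for-bit, and the first N iterations of a longer run
equal an N-iteration run with the same seed.

Experiments operate on the dataset's canonical count vector; clonotype
identities never influence the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from . import reference as ref
from .repio import ClonotypeTable
from .resampling import morisita_horn, rarefy_counts

__all__ = [
    "ExperimentConfig",
    "representativeness",
    "reproducibility",
    "sharing_experiment",
    "coverage_experiment",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid and ensemble settings for the subsampling experiments."""

    depths: tuple[int, ...] = ref.EXPERIMENT_DEPTHS
    n_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.depths):
            raise ValueError("depths must be positive")
        if self.n_iter < 2:
            raise ValueError("n_iter must be >= 2")

    def streams(self, depth_index: int, n: int | None = None) -> list[np.random.Generator]:
        """Per-iteration generators for one depth (prefix-stable in n)."""
        root = np.random.SeedSequence(self.seed)
        depth_child = root.spawn(len(self.depths))[depth_index]
        return [np.random.default_rng(s) for s in depth_child.spawn(n or self.n_iter)]


def _median_ci(values: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(values)),
        float(np.percentile(values, 2.5)),
        float(np.percentile(values, 97.5)),
    )


def representativeness(dataset: ClonotypeTable, config: ExperimentConfig) -> pd.DataFrame:
    """Similarity of single subsamples to their source repertoire.

    For each depth, draws ``n_iter`` subsamples and summarizes the
    Morisita-Horn similarity to the full dataset and the relative richness
    (subsample richness / dataset richness).
    """
    counts = dataset.counts
    richness = dataset.richness
    rows = []
    for di, depth in enumerate(config.depths):
        mh = np.empty(config.n_iter)
        rel = np.empty(config.n_iter)
        for i, rng in enumerate(config.streams(di)):
            sub = rarefy_counts(counts, depth, rng)
            mh[i] = morisita_horn(sub, counts)
            rel[i] = (sub > 0).sum() / richness
        m, lo, hi = _median_ci(mh)
        rm, rlo, rhi = _median_ci(rel)
        rows.append(
            {
                "depth": depth, "mh_median": m, "mh_lo": lo, "mh_hi": hi,
                "relative_richness_median": rm,
                "relative_richness_lo": rlo, "relative_richness_hi": rhi,
            }
        )
    return pd.DataFrame(rows)


def reproducibility(dataset: ClonotypeTable, config: ExperimentConfig) -> pd.DataFrame:
    """Agreement between independent subsamples at the same depth.

    For each depth, draws ``n_iter`` subsamples, pairs them disjointly
    (1st with 2nd, 3rd with 4th, ...) and summarizes the pairwise
    Morisita-Horn similarity.
    """
    counts = dataset.counts
    rows = []
    for di, depth in enumerate(config.depths):
        subs = [rarefy_counts(counts, depth, rng) for rng in config.streams(di)]
        mh = np.array(
            [morisita_horn(subs[k], subs[k + 1]) for k in range(0, len(subs) - 1, 2)]
        )
        m, lo, hi = _median_ci(mh)
        iqr = float(np.percentile(mh, 75) - np.percentile(mh, 25))
        rows.append(
            {"depth": depth, "mh_median": m, "mh_lo": lo, "mh_hi": hi, "mh_iqr": iqr}
        )
    return pd.DataFrame(rows)


def sharing_experiment(dataset: ClonotypeTable, config: ExperimentConfig) -> pd.DataFrame:
    """Triple-replicate sharing decomposition across the depth grid.

    For each depth, draws ``n_iter`` independent triples of subsamples;
    per triple, labels each union clonotype by the number of subsamples
    containing it and computes the percentage of the union that is private
    / shared by two / shared by three, plus the union richness. Medians
    and 95% percentile intervals are reported per depth.
    """
    counts = dataset.counts
    rows = []
    for di, depth in enumerate(config.depths):
        priv = np.empty(config.n_iter)
        sh2 = np.empty(config.n_iter)
        sh3 = np.empty(config.n_iter)
        union = np.empty(config.n_iter)
        for i, rng in enumerate(config.streams(di)):
            multiplicity = np.zeros(len(counts), dtype=np.int8)
            for _ in range(3):
                multiplicity += rarefy_counts(counts, depth, rng) > 0
            u = int((multiplicity > 0).sum())
            union[i] = u
            priv[i] = 100.0 * (multiplicity == 1).sum() / u
            sh2[i] = 100.0 * (multiplicity == 2).sum() / u
            sh3[i] = 100.0 * (multiplicity == 3).sum() / u
        row: dict = {"depth": depth}
        for name, values in (
            ("private_pct", priv),
            ("shared2_pct", sh2),
            ("shared3_pct", sh3),
            ("union_richness", union),
        ):
            m, lo, hi = _median_ci(values)
            row[f"{name}_median"] = m
            row[f"{name}_lo"] = lo
            row[f"{name}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def coverage_experiment(
    dataset: ClonotypeTable,
    config: ExperimentConfig,
    k_max: int | None = None,
) -> pd.DataFrame:
    """Cumulative richness coverage by an increasing number of subsamples.

    For each depth, draws a pool of ``n_iter`` subsamples; for each of
    ``n_iter`` random orderings of the pool, accumulates the union key set
    over the first k subsamples (k = 1..k_max) and divides by the dataset
    richness. The median coverage curve across orderings is reported.
    """
    counts = dataset.counts
    richness = dataset.richness
    k_max = k_max or min(config.n_iter, 20)
    if k_max > config.n_iter:
        raise ValueError("k_max cannot exceed n_iter")
    rows = []
    for di, depth in enumerate(config.depths):
        streams = config.streams(di, config.n_iter + 1)
        presence = np.stack(
            [rarefy_counts(counts, depth, rng) > 0 for rng in streams[:-1]]
        )
        order_rng = streams[-1]
        curves = np.empty((config.n_iter, k_max))
        for rep in range(config.n_iter):
            order = order_rng.permutation(config.n_iter)[:k_max]
            cum = np.logical_or.accumulate(presence[order], axis=0)
            curves[rep] = cum.sum(axis=1) / richness
        for k in range(k_max):
            m, lo, hi = _median_ci(curves[:, k])
            rows.append(
                {
                    "depth": depth, "k": k + 1,
                    "coverage_median": m, "coverage_lo": lo, "coverage_hi": hi,
                }
            )
    return pd.DataFrame(rows)
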