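"""Simulated TRB repertoires of known diversity.

A repertoire is modeled as a finite ranked Zipf-Mandelbrot population of
``R = 2*10^6`` clonotype labels with type probabilities

    pi_r = (r + q)^(-s) / Z,   Z = sum_{r=1..R} (r + q)^(-s)

The evenness of the repertoire is indexed by the parameter ``A`` (larger A
= flatter, more polyclonal distribution; A = 2 is the most skewed
condition). For each A, the rank exponent ``s_A`` is calibrated by
root-finding so that the expected number of distinct clonotypes observed
in a dataset of 6*10^5 sequences equals the published richness anchor
``N_A`` for that condition; the Mandelbrot offset ``q`` is kept at 0 (one
anchor, one free parameter) and the top-type probability is checked
against the cap ``B = 0.2``.

Dataset construction mirrors the published pipeline: a clonotype library
of 2*10^6 unique (TRBV, CDR3, TRBJ) labels is generated; the full token
total ``M_A`` is distributed over ranks by a multinomial draw from pi;
ranks are randomly assigned to library labels; and the repertoire is
rarefied without replacement to exactly 6*10^5 sequences.

The clonotype *identities* never enter any downstream statistic — only the
abundances do — so the library generator is a uniform combinatorial
labeler (random V/J assignment, CDR3 peptides starting with C and ending
with F, lengths 8-20 with mode 14, a consistent in-frame nucleotide
encoding), not a V(D)J recombination model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import reference as ref
from .exceptions import CalibrationError
from .repio import ClonotypeTable
from .resampling import rarefy_counts

__all__ = [
    "ZipfRankModel",
    "expected_distinct",
    "calibrate_model",
    "make_clonotype_library",
    "simulate_counts",
    "simulate_dataset",
    "SimulatedRepertoire",
]


@dataclass(frozen=True)
class ZipfRankModel:
    """Ranked type-probability population pi_r = (r+q)^(-s) / Z."""

    R: int = ref.LIBRARY_SIZE
    s: float = 1.0
    q: float = 0.0
    B: float = 0.2
    A: int | None = None  # evenness label this model was calibrated for

    def probabilities(self) -> np.ndarray:
        """Normalized, non-increasing rank probabilities (length R)."""
        ranks = np.arange(1, self.R + 1, dtype=float)
        weights = (ranks + self.q) ** (-self.s)
        return weights / weights.sum()


def expected_distinct(model: ZipfRankModel, depth: int) -> float:
    """Expected number of distinct types in *depth* multinomial draws.

    E[S_obs] = sum_r 1 - (1 - pi_r)^depth, evaluated stably through
    log1p/expm1 over all R ranks. By the equivalence between direct
    multinomial sampling at *depth* and multinomial sampling at any larger
    total followed by rarefaction to *depth*, this is also the expected
    richness of the constructed datasets.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    p = model.probabilities()
    return float(np.sum(-np.expm1(depth * np.log1p(-p))))


def calibrate_model(
    A: int,
    targets: Mapping[int, int] | None = None,
    R: int = ref.LIBRARY_SIZE,
    depth: int = ref.DATASET_SIZE,
    B: float = 0.2,
    rtol: float = 0.005,
) -> ZipfRankModel:
    """Calibrate the rank exponent s_A against the richness anchor for *A*.

    Root-finds s in [0, 3] such that ``expected_distinct(model, depth)``
    equals the anchor within *rtol* (default 0.5%), and checks the
    top-type probability cap pi_1 <= B.
    """
    targets = dict(targets or ref.RICHNESS_ANCHORS)
    if A not in targets:
        raise CalibrationError(f"no richness anchor for A={A}")
    target = targets[A]

    def objective(s: float) -> float:
        return expected_distinct(ZipfRankModel(R=R, s=s, B=B, A=A), depth) - target

    lo, hi = objective(0.0), objective(3.0)
    if lo * hi > 0:
        raise CalibrationError(
            f"A={A}: no rank exponent in [0, 3] reaches richness {target} "
            f"at depth {depth}"
        )
    s = brentq(objective, 0.0, 3.0, xtol=1e-8)
    model = ZipfRankModel(R=R, s=float(s), B=B, A=A)
    achieved = expected_distinct(model, depth)
    if abs(achieved - target) > rtol * target:
        raise CalibrationError(
            f"A={A}: calibration reached {achieved:.0f}, outside "
            f"{rtol:.1%} of {target}"
        )
    pi1 = model.probabilities()[0]
    if pi1 > B:
        raise CalibrationError(
            f"A={A}: top-type probability {pi1:.3f} exceeds the cap B={B}"
        )
    return model


# -- clonotype library -----------------------------------------------------

_AA20 = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")
# one fixed codon per amino acid: a deterministic in-frame encoding that we
# then diversify at the wobble position where synonymous codons allow it
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

# CDR3 peptide length distribution: 8..20, mode 14 (triangular weights)
_LENGTHS = np.arange(8, 21)
_LENGTH_W = np.minimum(_LENGTHS - 7, 21 - _LENGTHS).astype(float)
_LENGTH_P = _LENGTH_W / _LENGTH_W.sum()


def _random_cdr3(n: int, rng: np.random.Generator) -> list[str]:
    """n random CDR3 peptides, 'C'-started and 'F'-ended, vectorized."""
    lengths = rng.choice(_LENGTHS, size=n, p=_LENGTH_P)
    out: list[str] = [""] * n
    order = np.argsort(lengths, kind="stable")
    pos = 0
    for L in _LENGTHS:
        idx = order[pos : pos + int((lengths == L).sum())]
        pos += idx.size
        if idx.size == 0:
            continue
        middle = rng.integers(0, 20, size=(idx.size, L - 2))
        chars = _AA20[middle]
        seqs = (
            np.char.add(
                np.char.add(b"C", chars.view(f"S{L - 2}").ravel()), b"F"
            )
            .astype(str)
        )
        for i, s in zip(idx, seqs):
            out[int(i)] = s
    return out


def _encode_nt(aa: str) -> str:
    return "".join(_CODON[c] for c in aa)


def make_clonotype_library(
    n: int, rng: np.random.Generator, sample_id: str = "library"
) -> pd.DataFrame:
    """Generate *n* pairwise-distinct clonotype labels.

    Returns a DataFrame with columns ``v_gene``, ``cdr3_aa``, ``j_gene``
    and ``cdr3_nt`` (one consistent in-frame encoding per label). V and J
    are drawn uniformly from the bundled murine TRBV/TRBJ segment lists;
    duplicate (V, CDR3, J) combinations are re-drawn until all labels are
    unique.
    """
    if n < 1:
        raise ValueError("library size must be >= 1")
    # crude upper bound on the combinatorial space at the shortest length
    if n > len(ref.TRBV_GENES) * len(ref.TRBJ_GENES) * 20 ** 6:
        raise ValueError(f"library size {n} exceeds the combinatorial space")
    v = np.array(ref.TRBV_GENES)[rng.integers(0, len(ref.TRBV_GENES), size=n)]
    j = np.array(ref.TRBJ_GENES)[rng.integers(0, len(ref.TRBJ_GENES), size=n)]
    aa = np.array(_random_cdr3(n, rng), dtype=object)
    df = pd.DataFrame({"v_gene": v, "cdr3_aa": aa, "j_gene": j})
    while True:
        dup = df.duplicated(["v_gene", "cdr3_aa", "j_gene"]).to_numpy()
        n_dup = int(dup.sum())
        if n_dup == 0:
            break
        df.loc[dup, "v_gene"] = np.array(ref.TRBV_GENES)[
            rng.integers(0, len(ref.TRBV_GENES), size=n_dup)
        ]
        df.loc[dup, "cdr3_aa"] = np.array(_random_cdr3(n_dup, rng), dtype=object)
        df.loc[dup, "j_gene"] = np.array(ref.TRBJ_GENES)[
            rng.integers(0, len(ref.TRBJ_GENES), size=n_dup)
        ]
    df["cdr3_nt"] = [_encode_nt(a) for a in df["cdr3_aa"]]
    df.attrs["sample_id"] = sample_id
    return df.reset_index(drop=True)


def simulate_counts(
    model: ZipfRankModel,
    tokens: int,
    depth: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the abundance list and its rarefied dataset counts.

    Returns ``(z, c)``: ``z`` is the multinomial draw of *tokens*
    sequences over the R ranked type probabilities (sums to *tokens*
    exactly), and ``c`` is ``z`` rarefied without replacement to *depth*
    sequences.
    """
    p = model.probabilities()
    z = rng.multinomial(tokens, p)
    c = rarefy_counts(z, depth, rng)
    return z, c


@dataclass
class SimulatedRepertoire:
    """A simulated repertoire: calibrated model, library, abundances, dataset."""

    A: int
    model: ZipfRankModel
    library: pd.DataFrame | None  # R rows: v_gene, cdr3_aa, j_gene, cdr3_nt
    z: np.ndarray  # token counts per library row (sums to M_A)
    dataset: ClonotypeTable  # rarefied to the target dataset size


def simulate_dataset(
    A: int,
    rng: np.random.Generator,
    model: ZipfRankModel | None = None,
    library: pd.DataFrame | None = None,
    library_size: int = ref.LIBRARY_SIZE,
    dataset_size: int = ref.DATASET_SIZE,
    tokens: int | None = None,
    with_library: bool = True,
) -> SimulatedRepertoire:
    """Simulate one repertoire dataset for evenness condition *A*.

    Steps: calibrate (or reuse) the ranked Zipf model; multinomially
    distribute the full token total ``M_A`` over ranks; randomly permute
    the rank-to-label assignment; rarefy to *dataset_size* sequences
    without replacement; assemble the clonotype table.

    With ``with_library=False`` the unique-label generation is skipped and
    synthetic placeholder labels (rank identifiers) are used — abundance
    statistics are unaffected.
    """
    if model is None:
        model = calibrate_model(A, R=library_size, depth=dataset_size)
    if tokens is None:
        tokens = ref.TOKEN_TOTALS[A]
    z_ranked, c_ranked = simulate_counts(model, tokens, dataset_size, rng)
    perm = rng.permutation(model.R)  # rank i -> library row perm[i]
    z = np.zeros(model.R, dtype=z_ranked.dtype)
    z[perm] = z_ranked
    c = np.zeros(model.R, dtype=c_ranked.dtype)
    c[perm] = c_ranked
    observed = np.flatnonzero(c)
    if with_library and library is None:
        library = make_clonotype_library(model.R, rng)
    if library is not None:
        frame = library.iloc[observed][["v_gene", "cdr3_aa", "j_gene"]].copy()
    else:
        # synthetic placeholder labels; never used by abundance statistics
        frame = pd.DataFrame(
            {
                "v_gene": "TRBV0",
                "cdr3_aa": [f"CSIM{i}F" for i in observed],
                "j_gene": "TRBJ0",
            }
        )
    frame["count"] = c[observed]
    dataset = ClonotypeTable(frame, sample_id=f"A{A}-sim", validate=False)
    return SimulatedRepertoire(A=A, model=model, library=library, z=z, dataset=dataset)
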