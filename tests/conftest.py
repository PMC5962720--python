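"""Shared fixtures: toy tables, synthetic error fixtures, the simulated
A=3 repertoire used by the ensemble-level checks."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from repshannon import ClonotypeKey, ClonotypeTable
from repshannon.simulate import calibrate_model, simulate_dataset

_AA = "ACDEFGHIKLMNPQRSTVWY"


def table_from_counts(counts, sample_id="synthetic") -> ClonotypeTable:
    """Synthetic table with distinct generated keys and the given counts."""
    counts = np.asarray(counts)
    keys = {}
    letters = itertools.product(_AA, repeat=max(1, int(np.ceil(np.log(len(counts)) / np.log(20)))))
    for c, combo in zip(counts, letters):
        keys[ClonotypeKey("TRBV1", "C" + "".join(combo) + "F", "TRBJ1-1")] = int(c)
    return ClonotypeTable(keys, sample_id=sample_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240515)


@pytest.fixture
def toy_table():
    """Counts (4, 2, 1, 1): the worked example for the Shannon filter."""
    return ClonotypeTable(
        {
            ClonotypeKey("TRBV1", "CASSF", "TRBJ1-1"): 4,
            ClonotypeKey("TRBV2", "CASTF", "TRBJ1-2"): 2,
            ClonotypeKey("TRBV3", "CAAAF", "TRBJ1-3"): 1,
            ClonotypeKey("TRBV4", "CAAGF", "TRBJ1-4"): 1,
        },
        sample_id="toy",
    )


@pytest.fixture(scope="session")
def a3_model():
    return calibrate_model(3)


@pytest.fixture(scope="session")
def a3_dataset(a3_model):
    """One seeded realization of the simulated A=3 repertoire dataset.

    Label generation is skipped (placeholder labels): clonotype identities
    never enter the downstream abundance statistics.
    """
    rng = np.random.default_rng(1234)
    sim = simulate_dataset(3, rng, model=a3_model, with_library=False)
    return sim.dataset
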