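"""Rarefaction, Morisita-Horn, overlap decomposition and coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from repshannon import (
    ClonotypeKey,
    ClonotypeTable,
    morisita_horn,
    morisita_horn_tables,
    overlap_decomposition,
    pearson,
    rarefy,
    richness_coverage,
    sharing_spectrum,
)
from repshannon.reference import ALIQUOT_CELL_NUMBERS, ALIQUOT_SHANNON_EFFECTIVE

from conftest import table_from_counts


class TestRarefy:
    def test_depth_equal_to_total_returns_identical_table(self, toy_table, rng):
        with pytest.warns(UserWarning):
            out = rarefy(toy_table, toy_table.total, rng)
        assert out.to_dict() == toy_table.to_dict()

    def test_depth_beyond_total_returns_table_unchanged(self, toy_table, rng):
        with pytest.warns(UserWarning, match="unchanged"):
            out = rarefy(toy_table, 1_000_000, rng)
        assert out is toy_table

    def test_depth_below_one_raises(self, toy_table, rng):
        with pytest.raises(ValueError):
            rarefy(toy_table, 0, rng)

    def test_counts_bounded_by_input_and_total_exact(self, rng):
        t = table_from_counts(rng.integers(1, 50, size=30))
        sub = rarefy(t, 100, rng)
        assert sub.total == 100
        full = t.to_dict()
        for key, c in sub.to_dict().items():
            assert c <= full[key]

    def test_expected_richness_matches_hypergeometric_closed_form(self, rng):
        counts = np.arange(1, 11)  # 10 clonotypes, 55 sequences
        total, depth, reps = counts.sum(), 20, 2000
        # E[S] = sum_i 1 - C(T - n_i, d) / C(T, d)
        expected = sum(1 - stats.hypergeom.pmf(0, total, n, depth) for n in counts)
        t = table_from_counts(counts)
        observed = np.mean([rarefy(t, depth, rng).richness for _ in range(reps)])
        assert observed == pytest.approx(expected, rel=0.02)

    def test_rarefied_multinomial_equals_direct_multinomial(self, rng):
        """Drawing M tokens then rarefying to D is distributionally the
        same as drawing D tokens directly (chi-square on a 5-type toy)."""
        p = np.array([0.4, 0.3, 0.15, 0.1, 0.05])
        M, D, reps = 200, 20, 2000
        pooled = np.zeros(5)
        for _ in range(reps):
            z = rng.multinomial(M, p)
            pooled += rng.multivariate_hypergeometric(z, D)
        res = stats.chisquare(pooled, f_exp=reps * D * p)
        assert res.pvalue > 0.01


class TestMorisitaHorn:
    def test_self_similarity_is_one(self, rng):
        x = rng.integers(1, 100, size=20)
        assert morisita_horn(x, x) == pytest.approx(1.0)

    def test_disjoint_supports_are_zero(self):
        assert morisita_horn([5, 0, 0], [0, 3, 2]) == 0.0

    def test_reference_aliquot_example(self):
        mh = morisita_horn(ALIQUOT_CELL_NUMBERS, ALIQUOT_SHANNON_EFFECTIVE)
        assert mh == pytest.approx(0.996, abs=0.0005)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            morisita_horn([0, 0], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=20),
        y=st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=20),
        scale=st.floats(min_value=0.01, max_value=100),
    )
    def test_bounds_symmetry_scale_invariance(self, x, y, scale):
        n = min(len(x), len(y))
        x, y = np.asarray(x[:n], float), np.asarray(y[:n], float)
        if x.sum() == 0 or y.sum() == 0:
            return
        mh = morisita_horn(x, y)
        assert 0.0 <= mh <= 1.0 + 1e-12
        assert mh == pytest.approx(morisita_horn(y, x), abs=1e-12)
        assert mh == pytest.approx(morisita_horn(x * scale, y), rel=1e-9)

    def test_table_interface_aligns_union_keys(self):
        a = ClonotypeTable({ClonotypeKey("TRBV1", "CAF", "TRBJ1-1"): 5})
        b = ClonotypeTable(
            {
                ClonotypeKey("TRBV1", "CAF", "TRBJ1-1"): 5,
                ClonotypeKey("TRBV2", "CCF", "TRBJ1-2"): 5,
            }
        )
        assert 0 < morisita_horn_tables(a, b) < 1


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 3) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_reference_aliquot_example(self):
        r = pearson(ALIQUOT_CELL_NUMBERS, ALIQUOT_SHANNON_EFFECTIVE)
        assert r == pytest.approx(0.995, abs=0.0005)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


def _table(mapping, sample_id):
    keys = {
        "a": ClonotypeKey("TRBV1", "CAAF", "TRBJ1-1"),
        "b": ClonotypeKey("TRBV1", "CCCF", "TRBJ1-1"),
        "c": ClonotypeKey("TRBV2", "CDDF", "TRBJ1-2"),
        "d": ClonotypeKey("TRBV2", "CEEF", "TRBJ1-2"),
    }
    return ClonotypeTable({keys[k]: v for k, v in mapping.items()}, sample_id=sample_id)


@pytest.fixture
def triple():
    return [
        _table({"a": 5, "b": 1}, "T1"),
        _table({"a": 3, "c": 1}, "T2"),
        _table({"a": 2, "b": 2, "d": 1}, "T3"),
    ]


class TestOverlap:
    def test_hand_enumerated_toy(self, triple):
        dec = overlap_decomposition(triple)
        assert dec.counts == {1: 2, 2: 1, 3: 1}
        assert dec.union_richness == 4
        assert sum(dec.percentages.values()) == pytest.approx(100, abs=0.1)
        assert dec.cumulative_frequency_shared_all == pytest.approx((5 / 6, 3 / 4, 2 / 5))

    def test_identical_tables_fully_shared(self, toy_table):
        dec = overlap_decomposition([toy_table, toy_table, toy_table])
        assert dec.percentages[3] == pytest.approx(100)
        assert dec.cumulative_frequency_shared_all == pytest.approx((1.0, 1.0, 1.0))

    def test_disjoint_tables_fully_private(self):
        tables = [_table({k: 2}, k) for k in "abc"]
        dec = overlap_decomposition(tables)
        assert dec.percentages[1] == pytest.approx(100)

    def test_empty_table_raises(self, toy_table):
        with pytest.raises(ValueError):
            overlap_decomposition([toy_table, ClonotypeTable({})])


class TestSharingSpectrum:
    def test_hand_derived_toy_curves(self, triple):
        curves = sharing_spectrum(triple)
        t1 = curves[0]  # T1 canonical order: a (count 5), b (count 1)
        assert t1["shared_by_3"].tolist() == [1, 1]
        assert t1["shared_by_2"].tolist() == [0, 1]
        assert t1["shared_by_1"].tolist() == [0, 0]

    def test_identical_tables_give_identity_ramp(self, toy_table):
        curves = sharing_spectrum([toy_table, toy_table, toy_table])
        for df in curves:
            assert df["shared_by_3"].tolist() == list(range(1, toy_table.richness + 1))

    def test_final_values_partition_richness(self, rng, triple):
        for table, df in zip(triple, sharing_spectrum(triple)):
            last = df.iloc[-1]
            assert last["shared_by_1"] + last["shared_by_2"] + last["shared_by_3"] == table.richness


class TestRichnessCoverage:
    def test_repeated_subsample_gives_flat_curve(self, toy_table):
        cov = richness_coverage([toy_table] * 4, reference_richness=8)
        assert np.allclose(cov, 0.5)

    def test_partition_reaches_full_coverage(self):
        parts = [_table({"a": 1}, "p1"), _table({"b": 1, "c": 1}, "p2"), _table({"d": 1}, "p3")]
        cov = richness_coverage(parts, reference_richness=4)
        assert cov[-1] == 1.0
        assert np.all(np.diff(cov) >= 0)

    def test_bounded_by_sum_of_richnesses(self, rng):
        tables = [table_from_counts(rng.integers(1, 5, size=rng.integers(2, 10))) for _ in range(4)]
        ref = 50
        cov = richness_coverage(tables, ref)
        assert np.all(np.diff(cov) >= 0)
        assert cov[-1] <= min(1.0, sum(t.richness for t in tables) / ref)
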