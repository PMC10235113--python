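import numpy as np
import pytest
from hypothesis import given, strategies as st

from divkit.functional import fd_table, fdis, fdiv, feve, uniqueness

from oracles import naive_fdis, naive_fdiv, naive_feve, naive_uniqueness


def _random_instance(seed, max_s=8, max_axes=3):
    # k < s so that the S-1 leading-axis truncation used by the hull/MST
    # indices never discards information, keeping the naive all-axis
    # evaluation an exact reference
    rng = np.random.default_rng(seed)
    s = int(rng.integers(3, max_s + 1))
    k = int(rng.integers(1, min(max_axes, s - 1) + 1))
    x = rng.normal(size=(s, k))
    w = rng.dirichlet(np.ones(s))
    return x, w


class TestFDis:
    def test_single_species_zero(self):
        assert fdis(np.array([[1.0, 2.0]]), np.array([1.0])) == 0.0

    def test_two_equal_weights_half_distance(self):
        x = np.array([[0.0], [3.0]])
        assert fdis(x, np.array([0.5, 0.5])) == pytest.approx(1.5)

    def test_two_unequal_weights(self):
        # centroid at 0.9*0 + 0.1*1 = 0.1; FDis = 0.9*0.1 + 0.1*0.9
        x = np.array([[0.0], [1.0]])
        assert fdis(x, np.array([0.9, 0.1])) == pytest.approx(0.18)

    def test_scale_equivariance(self, rng):
        x, w = _random_instance(5)
        assert fdis(3.7 * x, w) == pytest.approx(3.7 * fdis(x, w))


class TestFDiv:
    def test_equilateral_triangle_equal_weights_is_one(self):
        x = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        assert fdiv(x, np.ones(3) / 3) == pytest.approx(1.0)

    def test_two_species_undefined(self):
        assert np.isnan(fdiv(np.array([[0.0], [1.0]]), np.array([0.5, 0.5])))

    def test_square_plus_center(self):
        # 4 unit-square vertices + center, equal weights: FDiv = 5/7 by
        # direct evaluation of the vertex-centroid formula
        x = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]], dtype=float)
        w = np.full(5, 0.2)
        assert fdiv(x, w) == pytest.approx(5 / 7)
        assert naive_fdiv(x, w) == pytest.approx(5 / 7)

    def test_collinear_degenerate_hull_reduced_dimension(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        val = fdiv(x, np.full(4, 0.25))
        assert 0 <= val <= 1

    def test_scale_invariance(self):
        x, w = _random_instance(11)
        assert fdiv(5.0 * x, w) == pytest.approx(fdiv(x, w))


class TestFEve:
    def test_equally_spaced_equal_weights_is_one(self):
        x = np.array([[0.0], [1.0], [2.0]])
        assert feve(x, np.ones(3) / 3) == pytest.approx(1.0)

    def test_two_species_undefined(self):
        assert np.isnan(feve(np.array([[0.0], [1.0]]), np.array([0.5, 0.5])))

    def test_unequal_spacing_hand_value(self):
        # spacings (1, 3), equal weights: PEW = (0.25, 0.75), threshold 1/2,
        # FEve = (0.25 + 0.5 - 0.5) / (1 - 0.5) = 0.5
        x = np.array([[0.0], [1.0], [4.0]])
        assert feve(x, np.ones(3) / 3) == pytest.approx(0.5)

    def test_scale_invariance(self):
        x, w = _random_instance(13)
        assert feve(2.5 * x, w) == pytest.approx(feve(x, w))


class TestUniqueness:
    def test_all_distances_one(self):
        d = 1 - np.eye(3)
        assert uniqueness(d, np.ones(3) / 3) == pytest.approx(1.0)

    def test_all_distances_zero(self):
        assert uniqueness(np.zeros((3, 3)), np.ones(3) / 3) == pytest.approx(0.0)

    def test_two_species_half_distance(self):
        d = np.array([[0, 0.5], [0.5, 0]])
        assert uniqueness(d, np.array([0.5, 0.5])) == pytest.approx(0.5)

    def test_single_dominant_species_undefined(self):
        d = 1 - np.eye(2)
        assert np.isnan(uniqueness(d, np.array([1.0, 0.0])))


@given(st.integers(0, 10_000))
def test_indices_match_naive_oracles(seed):
    """Each index equals its independently coded naive evaluation."""
    x, w = _random_instance(seed)
    rng = np.random.default_rng(seed + 1)
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
    d = d / (d.max() or 1)
    assert fdis(x, w) == pytest.approx(naive_fdis(x, w), abs=1e-10)
    assert fdiv(x, w) == pytest.approx(naive_fdiv(x, w), abs=1e-10)
    assert feve(x, w) == pytest.approx(naive_feve(x, w), abs=1e-10)
    assert uniqueness(d, w) == pytest.approx(naive_uniqueness(d, w), abs=1e-10)


@given(st.integers(0, 10_000))
def test_index_bounds(seed):
    x, w = _random_instance(seed, max_s=10)
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
    d = d / (d.max() or 1)
    assert fdis(x, w) >= 0
    assert 0 <= fdiv(x, w) <= 1
    assert 0 <= feve(x, w) <= 1
    assert 0 <= uniqueness(d, w) <= 1


@given(st.integers(0, 10_000))
def test_species_permutation_equivariance(seed):
    x, w = _random_instance(seed)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(w))
    assert fdis(x[perm], w[perm]) == pytest.approx(fdis(x, w), abs=1e-12)
    assert fdiv(x[perm], w[perm]) == pytest.approx(fdiv(x, w), abs=1e-12)
    assert feve(x[perm], w[perm]) == pytest.approx(feve(x, w), abs=1e-12)


class TestFDTable:
    def test_cardinality_sites_by_categories(self, small_dataset):
        table = fd_table(small_dataset)
        n_cat = len(small_dataset.traits.schema.categories)
        assert len(table) == small_dataset.community.n_sites * n_cat
        assert set(table["category"]) == set(small_dataset.traits.schema.categories)

    def test_richness_column_counts_present_species(self, small_dataset):
        table = fd_table(small_dataset)
        expected = dict(zip(small_dataset.community.site_ids,
                            small_dataset.community.richness()))
        for _, row in table.iterrows():
            assert row["S"] == expected[row["site"]]

    def test_species_column_order_irrelevant(self, small_dataset):
        from divkit.io import AnalysisDataset

        table1 = fd_table(small_dataset)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(small_dataset.community.species_ids))
        ds2 = AnalysisDataset(
            small_dataset.community.subset_species(perm),
            small_dataset.traits.subset(perm),
            small_dataset.tree, small_dataset.covariates,
            small_dataset.report)
        table2 = fd_table(ds2)
        merged = table1.merge(table2, on=["site", "category"], suffixes=("", "_p"))
        for col in ("FDis", "FDiv", "FEve", "Uniq"):
            np.testing.assert_allclose(merged[col], merged[f"{col}_p"],
                                       atol=1e-10, equal_nan=True)
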