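import warnings

import numpy as np
import pandas as pd
import pytest

import wheatqg as w


def random_psd_instance(rng, k=3):
    """Random (P, G, w) with P = G + E positive definite."""
    a = rng.standard_normal((k, k))
    G = a @ a.T + 0.5 * np.eye(k)
    b = rng.standard_normal((k, k))
    E = b @ b.T + 0.5 * np.eye(k)
    return G + E, G, rng.uniform(0.5, 2.0, size=k)


class TestSmithHazelCoefficients:
    def test_single_trait_equals_heritability(self):
        b = w.smith_hazel_coefficients(np.array([[4.0]]), np.array([[2.0]]), [1.0])
        assert b[0] == pytest.approx(0.5, abs=1e-14)

    def test_identity_phenotypic_covariance(self):
        rng = np.random.default_rng(0)
        _, G, wts = random_psd_instance(rng)
        b = w.smith_hazel_coefficients(np.eye(3), G, wts, bend=False)
        assert np.allclose(b, G @ wts, atol=1e-12)

    def test_matches_explicit_inverse_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            P, G, wts = random_psd_instance(rng)
            b = w.smith_hazel_coefficients(P, G, wts)
            oracle = np.linalg.inv(P) @ G @ wts
            assert np.allclose(b, oracle, atol=1e-10 * max(1, np.abs(oracle).max()))

    def test_singular_phenotypic_matrix_suggests_bending(self):
        P = np.array([[1.0, 1.0], [1.0, 1.0]])  # exactly singular
        G = 0.5 * np.eye(2)
        with pytest.raises(np.linalg.LinAlgError, match="bend"):
            w.smith_hazel_coefficients(P, G, [1.0, 1.0], bend=False)

    def test_bending_repairs_indefinite_estimates(self):
        G = np.array([[1.0, 1.2], [1.2, 1.0]])  # indefinite sampling estimate
        P = G + np.eye(2)
        b = w.smith_hazel_coefficients(P, G, [1.0, 1.0], bend=True)
        assert np.all(np.isfinite(b))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            w.smith_hazel_coefficients(np.eye(2), np.eye(3), [1.0, 1.0, 1.0])


class TestIndexValues:
    def test_unit_vector_selects_first_trait(self):
        means = pd.DataFrame({"A": [1.0, 2.0], "B": [5.0, 7.0]}, index=["G1", "G2"])
        si = w.index_values([1.0, 0.0], means)
        assert list(si) == [1.0, 2.0]

    def test_linearity_under_trait_shift(self):
        rng = np.random.default_rng(2)
        means = pd.DataFrame(rng.standard_normal((10, 2)), columns=["A", "B"])
        b = np.array([0.7, -0.3])
        shifted = means.copy()
        shifted["A"] += 5.0
        assert np.allclose(
            w.index_values(b, shifted), w.index_values(b, means) + 0.7 * 5.0
        )

    def test_tie_case_and_missing_values(self):
        means = pd.DataFrame(
            {"A": [2.0, 0.0, np.nan], "B": [3.0, 5.0, 1.0]},
            index=["G1", "G2", "G3"],
        )
        with pytest.warns(UserWarning, match="missing"):
            si = w.index_values([1.0, 1.0], means)
        assert si["G1"] == si["G2"] == 5.0
        assert np.isnan(si["G3"])


class TestDroughtIndex:
    def test_hand_computed_standardisation(self):
        si = pd.Series([1.0, 2.0, 3.0], index=["G1", "G2", "G3"])
        pi = pd.Series([2.0, 4.0, 6.0], index=["G1", "G2", "G3"])
        res = w.drought_index(si, pi)
        assert res.sd_si == pytest.approx(1.0)
        assert res.sd_pi == pytest.approx(2.0)
        assert np.allclose(res.di, [1.0, 2.0, 3.0])
        # invariant: DI == (SI/SD_SI + PI/SD_PI)/2 elementwise
        manual = 0.5 * (si / res.sd_si + pi / res.sd_pi)
        assert np.allclose(res.di, manual, atol=1e-10)

    def test_invariant_to_positive_rescaling_of_either_index(self):
        rng = np.random.default_rng(3)
        si = pd.Series(rng.standard_normal(20))
        pi = pd.Series(rng.standard_normal(20))
        base = w.drought_index(si, pi).di
        scaled = w.drought_index(7.0 * si, pi).di
        assert np.allclose(base, scaled, atol=1e-12)

    def test_constant_index_is_an_error(self):
        si = pd.Series([1.0, 1.0, 1.0])
        pi = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="constant"):
            w.drought_index(si, pi)

    def test_mismatched_genotype_sets_intersect_with_warning(self):
        si = pd.Series([1.0, 2.0, 3.0], index=["G1", "G2", "G3"])
        pi = pd.Series([1.0, 2.0, 4.0], index=["G2", "G3", "G4"])
        with pytest.warns(UserWarning, match="common"):
            res = w.drought_index(si, pi)
        assert list(res.di.index) == ["G2", "G3"]


class TestSelectExtremes:
    def test_top_and_bottom_disjoint(self):
        rng = np.random.default_rng(4)
        di = pd.Series(rng.standard_normal(198), index=[f"G{i:03d}" for i in range(198)])
        out = w.select_extremes(di, 20)
        assert len(out.top) == len(out.bottom) == 20
        assert not set(out.top) & set(out.bottom)
        assert min(di[g] for g in out.top) > max(di[g] for g in out.bottom)

    def test_boundary_tie_resolved_by_id_and_flagged(self):
        di = pd.Series(
            [3.0, 2.0, 2.0, 1.0], index=["Gb", "Gc", "Ga", "Gd"]
        )
        out = w.select_extremes(di, 2)
        assert out.top == ["Gb", "Ga"]  # tie at rank 2 -> lexicographic
        assert out.tie_at_boundary

    def test_k_equals_n_allowed_with_warning(self):
        di = pd.Series([1.0, 2.0, 3.0], index=["G1", "G2", "G3"])
        with pytest.warns(UserWarning, match="overlap"):
            out = w.select_extremes(di, 3)
        assert set(out.top) == set(out.bottom) == {"G1", "G2", "G3"}

    def test_k_above_n_is_an_error(self):
        di = pd.Series([1.0, 2.0], index=["G1", "G2"])
        with pytest.raises(ValueError, match="exceeds"):
            w.select_extremes(di, 3)


class TestIntersectYears:
    def test_basic_intersection_and_exclusives(self):
        res = w.intersect_years({"2020": {"A", "B", "C"}, "2021": {"B", "C", "D"}})
        assert res.common == {"B", "C"}
        assert res.exclusives["2020"] == {"A"}
        assert res.exclusives["2021"] == {"D"}

    def test_disjoint_sets_give_empty_intersection(self):
        res = w.intersect_years({"a": {"X"}, "b": {"Y"}})
        assert res.common == set()

    def test_three_sets_order_invariant(self):
        sets = {"a": {"1", "2", "3"}, "b": {"2", "3", "4"}, "c": {"3", "2"}}
        reordered = dict(reversed(list(sets.items())))
        assert (
            w.intersect_years(sets).common
            == w.intersect_years(reordered).common
            == {"2", "3"}
        )


class TestIndexOptimality:
    def test_smith_hazel_beats_random_indices_and_matches_accuracy_formula(self):
        """The Smith-Hazel index correlates with the aggregate genotypic
        value at least as well as random-weight indices, and the observed
        accuracy tracks sqrt(w'G P^-1 G w / w'G w)."""
        rng = np.random.default_rng(12)
        P, G, wts = random_psd_instance(rng, k=4)
        n = 2000
        g = rng.multivariate_normal(np.zeros(4), G, size=n)
        x = g + rng.multivariate_normal(np.zeros(4), P - G, size=n)
        h = g @ wts
        b = w.smith_hazel_coefficients(P, G, wts)
        acc = np.corrcoef(x @ b, h)[0, 1]
        expected = w.expected_index_accuracy(P, G, wts)
        assert acc == pytest.approx(expected, abs=0.05)
        losses = 0
        for _ in range(100):
            wr = rng.standard_normal(4)
            if np.corrcoef(x @ wr, h)[0, 1] > acc:
                losses += 1
        assert losses <= 2
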