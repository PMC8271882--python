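import numpy as np
import pytest

from ehecco import (
    WeightedSampleSet,
    ehecco_squared,
    ehecco_squared_oracle,
    mmd_squared,
    pairwise_distance_matrix,
)
from ehecco.errors import ConsistencyError, DimensionMismatchError
from ehecco.metric import (
    load_distance_matrix_csv,
    load_distance_matrix_npy,
    save_distance_matrix_csv,
    save_distance_matrix_npy,
)

from conftest import random_sample_set


class TestWeightedSampleSet:
    def test_uniform_default_weights(self, rng):
        s = WeightedSampleSet(rng.normal(size=(4, 3)), rng.normal(size=(4, 2)))
        np.testing.assert_allclose(s.weights, 0.25)

    @pytest.mark.parametrize(
        "weights, err",
        [
            ([0.5, 0.6], ValueError),  # does not sum to 1
            ([1.5, -0.5], ValueError),  # outside [0, 1]
            ([0.2, 0.3, 0.5], DimensionMismatchError),  # wrong length
        ],
    )
    def test_invalid_weights(self, rng, weights, err):
        with pytest.raises(err):
            WeightedSampleSet(rng.normal(size=(2, 3)), rng.normal(size=(2, 2)), weights)

    def test_count_mismatch(self, rng):
        with pytest.raises(DimensionMismatchError):
            WeightedSampleSet(rng.normal(size=(3, 2)), rng.normal(size=(4, 2)))


class TestMMD:
    def test_identical_sets_zero(self, rng):
        X = rng.normal(size=(6, 3))
        assert mmd_squared(X, X.copy(), 1.3) == 0.0

    def test_singleton_closed_form(self):
        # N=M=1, x=0, z=1: 2(1 - exp(-1/(2 b^2))) at effective bandwidth b
        val = mmd_squared([[0.0]], [[1.0]], 1.0)  # default convention: b = 2 sigma
        assert val == pytest.approx(2 * (1 - np.exp(-1 / 8)), abs=1e-12)
        assert val == pytest.approx(0.2350062, abs=1e-6)
        val_var = mmd_squared([[0.0]], [[1.0]], 1.0, convention="variance")
        assert val_var == pytest.approx(2 * (1 - np.exp(-1 / 4)), abs=1e-12)

    def test_separation_limit(self):
        assert mmd_squared([[0.0]], [[1e6]], 1.0) == pytest.approx(2.0, abs=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(DimensionMismatchError):
            mmd_squared(rng.normal(size=(3, 2)), rng.normal(size=(3, 3)), 1.0)


class TestEheccoEstimator:
    def test_identical_sets_zero(self, rng):
        P = random_sample_set(rng, 6, 3, 2)
        assert ehecco_squared(P, P, 1.0, 1.0) == 0.0
        assert ehecco_squared_oracle(P, P, 1.0, 1.0) <= 1e-12

    def test_matches_oracle_on_seeded_instance(self, rng):
        P = random_sample_set(rng, 5, 3, 2)
        R = random_sample_set(rng, 5, 3, 2)
        fast = ehecco_squared(P, R, 1.0, 1.0)
        slow = ehecco_squared_oracle(P, R, 1.0, 1.0)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_symmetry(self, rng):
        for _ in range(20):
            P = random_sample_set(rng, int(rng.integers(1, 10)), 3, 2)
            R = random_sample_set(rng, int(rng.integers(1, 10)), 3, 2)
            sp, sl = rng.uniform(0.3, 3.0, 2)
            assert ehecco_squared(P, R, sp, sl) == pytest.approx(
                ehecco_squared(R, P, sp, sl), abs=1e-12
            )

    def test_singleton_closed_form(self):
        P = WeightedSampleSet([[0.0]], [[0.0]])
        R = WeightedSampleSet([[1.0]], [[2.0]])
        kphi = np.exp(-1 / 2)
        kpsi = np.exp(-4 / 2)
        expected = 2 * (1 - kphi * kpsi)
        assert ehecco_squared(P, R, 1.0, 1.0) == pytest.approx(expected, abs=1e-12)
        assert ehecco_squared_oracle(P, R, 1.0, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_weight_concentration_limit(self, rng):
        # all mass on one sample per set -> singleton closed form, exactly
        n, m = 4, 5
        P = WeightedSampleSet(
            rng.normal(size=(n, 2)), rng.normal(size=(n, 2)),
            np.eye(n)[1],
        )
        R = WeightedSampleSet(
            rng.normal(size=(m, 2)), rng.normal(size=(m, 2)),
            np.eye(m)[3],
        )
        kphi = np.exp(-np.sum((P.primary[1] - R.primary[3]) ** 2) / 2)
        kpsi = np.exp(-np.sum((P.latent[1] - R.latent[3]) ** 2) / 2)
        assert ehecco_squared(P, R, 1.0, 1.0) == pytest.approx(2 * (1 - kphi * kpsi), rel=1e-12)

    def test_reduction_to_mmd(self, rng):
        # constant latent samples make the latent kernel all-ones; with
        # uniform weights the joint estimator collapses to the marginal MMD
        X = rng.normal(size=(6, 3))
        Z = rng.normal(size=(4, 3))
        P = WeightedSampleSet(X, np.zeros((6, 1)))
        R = WeightedSampleSet(Z, np.zeros((4, 1)))
        joint = ehecco_squared(P, R, 0.9, 1.0)
        marginal = mmd_squared(X, Z, 0.9, convention="none")
        assert joint == pytest.approx(marginal, abs=1e-12)

    def test_dimension_mismatches_reported_separately(self, rng):
        P = random_sample_set(rng, 3, 3, 2)
        with pytest.raises(DimensionMismatchError, match="V"):
            ehecco_squared(P, random_sample_set(rng, 3, 4, 2), 1.0, 1.0)
        with pytest.raises(DimensionMismatchError, match="Q"):
            ehecco_squared(P, random_sample_set(rng, 3, 3, 3), 1.0, 1.0)

    def test_large_negative_raw_value_raises(self, rng, monkeypatch):
        from ehecco import metric as metric_mod

        P = random_sample_set(rng, 3, 2, 2)
        # self-kernel terms vanish, cross term stays: raw value -2 << -1e-9
        calls = {"n": 0}

        def broken_kernel(A, B, s):
            calls["n"] += 1
            fill = 0.0 if calls["n"] <= 4 else 1.0
            return np.full((len(A), len(B)), fill)

        monkeypatch.setattr(metric_mod, "gaussian_kernel_matrix", broken_kernel)
        with pytest.raises(ConsistencyError):
            metric_mod.ehecco_squared(P, P, 1.0, 1.0)


class TestPairwiseDistanceMatrix:
    def test_symmetric_zero_diagonal(self, rng):
        reps = [random_sample_set(rng, 4, 3, 2) for _ in range(4)]
        D = pairwise_distance_matrix(reps, 1.0, 1.0)
        np.testing.assert_array_equal(D, D.T)
        np.testing.assert_array_equal(np.diag(D), 0.0)

    def test_entries_match_oracle(self, rng):
        reps = [random_sample_set(rng, 4, 2, 2) for _ in range(3)]
        D = pairwise_distance_matrix(reps, 0.8, 1.2)
        for i in range(3):
            for j in range(i + 1, 3):
                expected = np.sqrt(ehecco_squared_oracle(reps[i], reps[j], 0.8, 1.2))
                assert D[i, j] == pytest.approx(expected, rel=1e-10)

    def test_duplicate_representation_zero_distance(self, rng):
        base = random_sample_set(rng, 4, 3, 2)
        reps = [base, base, random_sample_set(rng, 4, 3, 2)]
        D = pairwise_distance_matrix(reps, 1.0, 1.0)
        assert D[0, 1] == 0.0

    def test_squared_flag(self, rng):
        reps = [random_sample_set(rng, 3, 2, 1) for _ in range(3)]
        D = pairwise_distance_matrix(reps, 1.0, 1.0)
        D2 = pairwise_distance_matrix(reps, 1.0, 1.0, squared=True)
        np.testing.assert_allclose(D**2, D2, atol=1e-12)

    def test_incompatible_rep_names_index(self, rng):
        reps = [random_sample_set(rng, 3, 2, 2), random_sample_set(rng, 3, 5, 2)]
        with pytest.raises(DimensionMismatchError, match="representation 1"):
            pairwise_distance_matrix(reps, 1.0, 1.0)


def test_distance_matrix_io_round_trip(tmp_path, rng):
    D = np.abs(rng.normal(size=(3, 3)))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    ids = ["rec_a", "rec_b", "rec_c"]
    csv = tmp_path / "D.csv"
    save_distance_matrix_csv(D, ids, csv)
    D_csv, ids_back = load_distance_matrix_csv(csv)
    assert ids_back == ids
    np.testing.assert_allclose(D_csv, D, rtol=1e-12)
    npy = tmp_path / "D.npy"
    save_distance_matrix_npy(D, npy)
    np.testing.assert_array_equal(load_distance_matrix_npy(npy), D)  # exact
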