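import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmfimpute import (
    estimate_rank,
    generate_fixture,
    k_schedule,
    masked_nmf,
    nmf_impute,
    nrmse,
    observed_loss,
    reconstruction_error,
    simulate_mcar,
    weighted_reconstruction,
)
from nmfimpute.nmf_core import EnsembleModel, FactorPair

from conftest import make_matrix


class TestObservedLoss:
    def test_exact_reconstruction_is_zero(self):
        B = np.array([[1.0], [2.0]])
        C = np.array([[3.0, 4.0]])
        m = make_matrix(B @ C, scale="log10")
        assert observed_loss(m, (B, C)) == 0.0

    def test_hand_computed_residual(self):
        # X = [[2, 1], [1, 1]] vs BC = ones: only the (0,0) cell errs -> 1
        m = make_matrix([[2.0, 1.0], [1.0, 1.0]], scale="log10")
        B = np.array([[1.0], [1.0]])
        C = np.array([[1.0, 1.0]])
        assert observed_loss(m, (B, C)) == pytest.approx(1.0)

    def test_masking_removes_contribution(self):
        vals = np.array([[2.0, 1.0], [1.0, 1.0]])
        B, C = np.array([[1.0], [1.0]]), np.array([[1.0, 1.0]])
        full = observed_loss(make_matrix(vals, scale="log10"), (B, C))
        vals_masked = vals.copy()
        vals_masked[0, 0] = np.nan  # hide the only erring cell
        masked = observed_loss(make_matrix(vals_masked, scale="log10"), (B, C))
        assert full == pytest.approx(1.0)
        assert masked == pytest.approx(0.0)


class TestMaskedNMF:
    def test_loss_monotone_nonincreasing(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            vals = rng.uniform(0.5, 5.0, size=(12, 8))
            vals[rng.random((12, 8)) < 0.2] = np.nan
            vals[:, 0] = rng.uniform(0.5, 5.0, 12)  # keep every row observed
            m = make_matrix(vals, scale="log10")
            f = masked_nmf(m, k=int(rng.integers(1, 6)), seed=trial, max_iter=120)
            diffs = np.diff(f.loss_history)
            assert np.all(diffs <= 1e-9)

    def test_rank1_exact_recovery(self):
        rng = np.random.default_rng(2)
        b = rng.uniform(0.5, 2.0, size=(12, 1))
        c = rng.uniform(0.5, 2.0, size=(1, 9))
        m = make_matrix(b @ c, scale="log10")
        f = masked_nmf(m, k=1, seed=0, tol=1e-12, max_iter=2000)
        rel = np.linalg.norm(m.values - f.reconstruction()) / np.linalg.norm(m.values)
        assert rel < 1e-4

    def test_full_rank_capacity(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.5, 3.0, size=(6, 6))
        m = make_matrix(vals, scale="log10")
        f = masked_nmf(m, k=6, seed=1, tol=1e-14, max_iter=5000)
        assert f.final_loss < 1e-6 * np.sum(vals**2)

    def test_deterministic_given_seed(self, small_complete):
        from nmfimpute import log10_transform

        ml, _ = log10_transform(small_complete)
        f1 = masked_nmf(ml, k=3, seed=9, max_iter=50)
        f2 = masked_nmf(ml, k=3, seed=9, max_iter=50)
        np.testing.assert_array_equal(f1.B, f2.B)
        np.testing.assert_array_equal(f1.C, f2.C)

    def test_k_out_of_range(self, small_complete):
        with pytest.raises(ValueError, match="out of range"):
            masked_nmf(small_complete, k=21)

    def test_all_missing_metabolite_rejected(self):
        vals = np.array([[1.0, 2.0], [np.nan, np.nan], [3.0, 4.0]])
        m = make_matrix(vals, scale="log10")
        with pytest.raises(ValueError, match="no observed"):
            masked_nmf(m, k=1)

    def test_matches_unmasked_reference_nmf(self):
        """With a full mask the masked updates solve the same problem as a
        plain NMF; both should drive a 4x4 full-K fit to ~zero loss."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(4)
        vals = rng.uniform(0.5, 3.0, size=(4, 4))
        m = make_matrix(vals, scale="log10")
        ours = masked_nmf(m, k=4, seed=0, tol=1e-14, max_iter=8000)
        # identical init: replicate the seeded (0,1] uniform scaled draw
        rng0 = np.random.default_rng(0)
        scale = np.sqrt(vals.mean() / 4)
        B0 = (1.0 - rng0.random((4, 4))) * scale
        C0 = (1.0 - rng0.random((4, 4))) * scale
        ref = NMF(
            n_components=4, init="custom", solver="mu", tol=1e-14, max_iter=8000
        )
        W = ref.fit_transform(vals, W=B0.copy(), H=C0.copy())
        ref_loss = np.sum((vals - W @ ref.components_) ** 2)
        assert abs(ours.final_loss - ref_loss) < 1e-6


class TestEstimateRank:
    def test_noiseless_rank3_fixture(self):
        m = generate_fixture(25, 12, 3, noise_sd=0.0, seed=8)
        ml = make_matrix(np.log10(m.values), scale="log10")
        assert estimate_rank(ml) == 3

    def test_diagonal_full_rank(self):
        n = 6
        vals = np.eye(n) * 5.0 + 0.0
        m = make_matrix(np.where(vals > 0, vals, 1e-9), scale="log10")
        assert estimate_rank(m) == n

    def test_never_exceeds_min_dim(self, small_complete):
        ml = make_matrix(np.log10(small_complete.values), scale="log10")
        assert estimate_rank(ml) <= 20


class TestKSchedule:
    @pytest.mark.parametrize(
        "rank,n,i,j,expected",
        [
            (15, 20, 60, 40, list(range(5, 25))),  # centred, unclamped
            (3, 20, 200, 100, list(range(1, 21))),  # lower clamp
            (1, 20, 8, 8, list(range(1, 9))),  # truncation: matrix smaller than N
            (38, 20, 60, 40, list(range(21, 41))),  # upper clamp shifts down
        ],
    )
    def test_schedule(self, rank, n, i, j, expected):
        assert k_schedule(rank, n, i, j) == expected

    def test_exact_model_count_when_unclamped(self):
        ks = k_schedule(15, 20, 60, 40)
        assert len(ks) == 20
        assert np.all(np.diff(ks) == 1)


class TestReconstructionError:
    def test_perfect_is_zero(self, small_complete):
        from nmfimpute import log10_transform

        ml, _ = log10_transform(small_complete)
        assert reconstruction_error(ml, ml.values) == 0.0

    def test_hand_computed_mad(self):
        m = make_matrix([[2.0, 4.0], [1.0, 1.0]], scale="log10")
        x_hat = np.array([[3.0, 3.0], [1.0, 1.0]])
        assert reconstruction_error(m, x_hat) == pytest.approx(0.5)  # (1+1+0+0)/4

    def test_ignores_unobserved_cells(self):
        m = make_matrix([[2.0, np.nan], [1.0, 1.0]], scale="log10")
        x_hat = np.array([[2.0, 999.0], [1.0, 1.0]])
        assert reconstruction_error(m, x_hat) == 0.0


class TestWeightedReconstruction:
    def test_single_model_weight_one(self):
        x = np.ones((2, 2))
        ens = weighted_reconstruction([EnsembleModel(1, x, 0.3)])
        assert ens.weights == pytest.approx([1.0])
        np.testing.assert_array_equal(ens.x_hat, x)

    def test_equal_errors_average(self):
        a, b = np.zeros((2, 2)), np.full((2, 2), 2.0)
        ens = weighted_reconstruction([EnsembleModel(1, a, 0.7), EnsembleModel(2, b, 0.7)])
        np.testing.assert_allclose(ens.weights, [0.5, 0.5])
        np.testing.assert_allclose(ens.x_hat, np.ones((2, 2)))

    def test_softmax_hand_values(self):
        a, b = np.zeros((1, 2)), np.ones((1, 2))
        ens = weighted_reconstruction(
            [EnsembleModel(1, a, 0.0), EnsembleModel(2, b, np.log(3.0))]
        )
        np.testing.assert_allclose(ens.weights, [0.75, 0.25], atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=500.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_weights_sum_to_one(self, ds):
        models = [EnsembleModel(k, np.zeros((2, 2)), d) for k, d in enumerate(ds)]
        ens = weighted_reconstruction(models)
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(ens.weights > 0)


class TestNmfImpute:
    def test_complete_matrix_identity(self, small_complete):
        res = nmf_impute(small_complete, seed=0, max_iter=30)
        np.testing.assert_array_equal(res.values, small_complete.values)
        assert res.imputed_mask.sum() == 0

    def test_observed_entries_bit_exact(self):
        truth = generate_fixture(50, 20, 4, 0.05, seed=21)
        sim = simulate_mcar(truth, 15, 0, seed=22)
        res = nmf_impute(sim.masked, seed=23, max_iter=100)
        obs = sim.masked.observed
        assert np.array_equal(res.values[obs], sim.masked.values[obs])
        assert np.all(res.values > 0)

    def test_default_ensemble_has_twenty_models(self):
        # rank ~ min(I,J) after noise; schedule must still hold 20 models
        truth = generate_fixture(100, 45, 15, 0.05, seed=31)
        sim = simulate_mcar(truth, 10, 0, seed=32)
        res = nmf_impute(sim.masked, seed=33, max_iter=40)
        assert len(res.ensemble.models) == 20
        assert np.all(np.diff(res.ensemble.ks) == 1)

    def test_recovers_low_rank_structure(self):
        truth = generate_fixture(100, 30, 5, 0.01, seed=41)
        sim = simulate_mcar(truth, 10, 0, seed=42)
        res = nmf_impute(sim.masked, seed=43)
        assert nrmse(truth, res, sim.theta_s) < 0.15

    def test_ensemble_beats_worst_member_on_average(self):
        """The softmax-weighted ensemble should never do worse on average
        than the single worst K in its schedule."""
        ens_scores, worst_scores = [], []
        for s in range(20):
            truth = generate_fixture(40, 20, 4, 0.02, seed=500 + s)
            sim = simulate_mcar(truth, 10, 0, seed=600 + s)
            res = nmf_impute(sim.masked, seed=700 + s, max_iter=200)
            ens_scores.append(nrmse(truth, res, sim.theta_s))
            per_k = [
                nrmse(truth, res.model_imputation(k, sim.masked), sim.theta_s)
                for k in res.ensemble.ks
            ]
            worst_scores.append(max(per_k))
        assert np.mean(ens_scores) <= np.mean(worst_scores)
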