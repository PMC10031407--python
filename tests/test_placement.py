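"""Sensor placement: standardisation, PCA basis, LDA, elastic net, top-k."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from wingsense.fixtures import make_fixture
from wingsense.placement import (
    DegenerateClassesError, SSPOCParams, elastic_net_sensors, lda_direction,
    pca_basis, select_top_k, sspoc, standardize,
)


class TestStandardize:
    def test_zero_mean_unit_variance(self, rng):
        X = rng.normal(3.0, 2.0, (50, 8))
        Z, tf = standardize(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_constant_column_maps_to_zero(self, rng):
        X = rng.normal(size=(30, 4))
        X[:, 2] = 7.7
        Z, tf = standardize(X)
        assert np.all(Z[:, 2] == 0.0)
        assert tf.scale[2] == 0.0

    def test_stored_transform_reproduces(self, rng):
        X = rng.normal(size=(40, 6))
        Z, tf = standardize(X)
        assert np.allclose(tf.transform(X), Z)


class TestPcaBasis:
    def test_collinear_data_span_recovered(self, rng):
        direction = np.array([3.0, -4.0, 0.0, 0.0]) / 5.0
        data = np.outer(rng.normal(size=100), direction)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Psi = pca_basis(data, 1)
        cos = np.abs(Psi[:, 0] @ direction)
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_orthonormal_columns(self, rng):
        Z = rng.normal(size=(60, 20))
        Psi = pca_basis(Z, 5)
        assert np.allclose(Psi.T @ Psi, np.eye(5), atol=1e-10)

    def test_explained_variance_non_increasing(self, rng):
        Z = rng.normal(size=(80, 15)) * np.linspace(3, 0.5, 15)
        Psi = pca_basis(Z, 6)
        Zc = Z - Z.mean(0)
        var = ((Zc @ Psi) ** 2).sum(axis=0)
        assert np.all(np.diff(var) <= 1e-9)

    def test_deterministic_sign(self, rng):
        Z = rng.normal(size=(50, 10))
        a = pca_basis(Z, 3)
        b = pca_basis(Z.copy(), 3)
        assert np.array_equal(a, b)
        for j in range(3):
            assert a[np.argmax(np.abs(a[:, j])), j] > 0


class TestLdaDirection:
    def test_isotropic_clusters_recover_displacement_axis(self, rng):
        mu = np.array([2.5, 0.0, 0.0])
        a = rng.normal(size=(200, 3))
        b = rng.normal(size=(200, 3)) + mu
        P = np.vstack([a, b])
        labels = np.r_[np.zeros(200, bool), np.ones(200, bool)]
        w = lda_direction(P, labels)
        assert np.abs(w @ np.array([1.0, 0, 0])) == pytest.approx(1.0, abs=0.05)
        assert w[0] > 0   # rotation class projects positive

    def test_matches_sklearn_direction(self, rng):
        """Cross-check the Fisher solve against sklearn's LDA coefficients."""
        a = rng.normal(size=(100, 4)) @ np.diag([1, 2, 0.5, 1.5])
        b = rng.normal(size=(100, 4)) + np.array([1.0, -0.5, 0.3, 0.0])
        P = np.vstack([a, b])
        labels = np.r_[np.zeros(100, bool), np.ones(100, bool)]
        w = lda_direction(P, labels, ridge=0.0)
        ref = LinearDiscriminantAnalysis(solver="eigen").fit(P, labels).coef_[0]
        ref = ref / np.linalg.norm(ref)
        assert np.abs(w @ ref) == pytest.approx(1.0, abs=1e-6)

    def test_label_swap_flips_before_orientation(self, rng):
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 3)) + 1.0
        P = np.vstack([a, b])
        labels = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        w1 = lda_direction(P, labels)
        w2 = lda_direction(P, ~labels)
        # orientation normalisation makes both point at their own class 1
        assert np.allclose(w1, -w2, atol=1e-9)

    def test_identical_means_rejected(self):
        P = np.tile(np.array([[1.0, 2.0]]), (10, 1))
        labels = np.r_[np.zeros(5, bool), np.ones(5, bool)]
        with pytest.raises(DegenerateClassesError):
            lda_direction(P, labels)


class TestElasticNet:
    def test_identity_basis_is_self_sparse(self):
        """If Psi is the first m columns of the identity, the minimiser
        puts s_i = w_i on those coordinates and zero elsewhere."""
        n, m = 30, 3
        Psi = np.eye(n)[:, :m]
        w = np.array([0.5, -1.2, 0.8])
        for lam in (0.0, 0.5, 0.9):
            s = elastic_net_sensors(Psi, w, lam)
            assert np.allclose(s[:m], w, atol=1e-6)
            assert np.allclose(s[m:], 0.0, atol=1e-8)

    def test_ridge_limit_matches_least_norm_solution(self, rng):
        """At lam = 0 the program reduces to min ||s||_2 s.t. Psi^T s = w,
        whose closed form is Psi (Psi^T Psi)^-1 w."""
        A = rng.normal(size=(40, 3))
        Psi, _ = np.linalg.qr(A)
        w = rng.normal(size=3)
        s = elastic_net_sensors(Psi, w, lam=0.0)
        assert np.allclose(s, Psi @ w, atol=1e-8)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 0.9, 1.0])
    def test_feasibility_residual(self, lam, rng):
        Z = rng.normal(size=(120, 200))
        Psi = pca_basis(Z, 3)
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        s = elastic_net_sensors(Psi, w, lam)
        assert np.abs(Psi.T @ s - w).max() < 1e-6

    def test_sparsity_increases_with_lam(self, rng):
        Z = rng.normal(size=(150, 300))
        Psi = pca_basis(Z, 3)
        w = np.array([0.8, -0.5, 0.33])
        s_ridge = elastic_net_sensors(Psi, w, 0.0)
        s_sparse = elastic_net_sensors(Psi, w, 0.9)
        thr = 1e-6 * np.abs(s_sparse).max()
        n_sparse = int((np.abs(s_sparse) > thr).sum())
        n_ridge = int((np.abs(s_ridge) > 1e-6 * np.abs(s_ridge).max()).sum())
        assert n_sparse <= n_ridge
        assert n_sparse <= 3 * 10   # few nonzeros per basis direction

    def test_objective_not_worse_than_least_norm_point(self, rng):
        """The solver's objective must beat the feasible ridge point."""
        A = rng.normal(size=(60, 3))
        Psi, _ = np.linalg.qr(A)
        w = rng.normal(size=3)
        lam = 0.9
        s = elastic_net_sensors(Psi, w, lam)
        ref = Psi @ w
        obj = lambda v: lam * np.abs(v).sum() + (1 - lam) * (v @ v)
        assert obj(s) <= obj(ref) + 1e-9


class TestSelectTopK:
    def test_largest_magnitudes_selected(self):
        s = np.array([0.9, -0.8, 0.01, 0.0, 0.0])
        out = select_top_k(s, 2)
        assert out.selected.tolist() == [0, 1]

    def test_all_zero_warns_and_uses_index_order(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = select_top_k(np.zeros(6), 3)
        assert out.selected.tolist() == [0, 1, 2]

    def test_k_equals_n(self, rng):
        s = rng.normal(size=7)
        assert sorted(select_top_k(s, 7).selected.tolist()) == list(range(7))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ties_break_to_lower_index(self, seed):
        r = np.random.default_rng(seed)
        s = r.choice([0.0, 0.5, -0.5], size=12)
        out = select_top_k(s, 4)
        mags = np.abs(s)[out.selected]
        assert np.all(np.diff(mags) <= 0)
        for a, b in zip(out.selected, out.selected[1:]):
            if np.abs(s[a]) == np.abs(s[b]):
                assert a < b


class TestSspocEndToEnd:
    def test_deterministic_given_inputs(self):
        flap, rot = make_fixture("separable-spikes", seed=5)
        p = SSPOCParams(n_sensors=5)
        a = sspoc(flap.first_spike[:90], rot.first_spike[:90], p)
        b = sspoc(flap.first_spike[:90], rot.first_spike[:90], p)
        assert np.array_equal(a.selected, b.selected)
        assert np.array_equal(a.weights, b.weights)

    def test_elastic_net_ranks_informative_direction_first(self, rng):
        """When the basis contains the informative node's direction, the
        reconstruction concentrates its weight there."""
        n = 40
        e = np.zeros((n, 3))
        e[7, 0] = 1.0                      # informative node direction
        e[:, 1:] = rng.normal(size=(n, 2))
        Psi, _ = np.linalg.qr(e)
        w = np.array([0.95, 0.2, 0.1])     # discriminant mostly along it
        s = elastic_net_sensors(Psi, w, 0.9)
        assert np.argmax(np.abs(s)) == 7
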