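"""SPD geometry: super-trials, SCM, distance, Fréchet mean, tangent, MDM.

Reference values come from numerically independent routes: scipy.linalg's
Schur–Padé logm/sqrtm (vs the package's eigendecomposition route), naive
loops for the covariance estimator, and first-order stationarity for the
Fréchet mean.
"""

import numpy as np
import pytest
import scipy.linalg as sla
from hypothesis import given, settings
from hypothesis import strategies as st

from streambci.riemann import (
    MDM,
    MeanConvergenceError,
    make_supertrial,
    riemannian_distance,
    riemannian_mean,
    scm,
    tangent_dim,
    tangent_project,
    tangent_vectors,
    upper,
)
from tests.conftest import random_spd


def _ref_distance(a, b):
    """Affine-invariant distance via scipy's Schur-based matrix functions."""
    a_isqrt = sla.inv(sla.sqrtm(a))
    return np.linalg.norm(sla.logm(a_isqrt @ b @ a_isqrt), "fro")


def _ref_tangent(sigma, base):
    b_isqrt = sla.inv(sla.sqrtm(base))
    return sla.logm(b_isqrt @ sigma @ b_isqrt)


class TestSuperTrial:
    def test_dimensions_and_top_block(self, rng):
        p1 = rng.normal(size=(6, 600))
        xi = rng.normal(size=(6, 600))
        st = make_supertrial(p1, xi)
        assert st.shape == (12, 600)
        assert np.array_equal(st[:6], p1)

    def test_zero_epoch_gives_zero_bottom_block(self, rng):
        st = make_supertrial(rng.normal(size=(6, 10)), np.zeros((6, 10)))
        assert np.allclose(st[6:], 0.0)

    def test_column_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            make_supertrial(rng.normal(size=(6, 10)), rng.normal(size=(6, 11)))


class TestScm:
    def test_orthonormal_rows_give_identity(self):
        n = 25
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(n, 4)))
        x = q.T * np.sqrt(n - 1)
        assert np.allclose(scm(x), np.eye(4), atol=1e-12)

    def test_matches_naive_two_loop_computation(self, rng):
        x = rng.normal(size=(12, 600))
        sigma = scm(x)
        d, n = x.shape
        naive = np.zeros((d, d))
        for i in range(d):
            for j in range(d):
                naive[i, j] = np.dot(x[i], x[j]) / (n - 1)
        assert np.allclose(sigma, naive, atol=1e-12)

    def test_not_mean_centered_by_default(self, rng):
        x = rng.normal(size=(3, 100)) + 5.0
        assert scm(x)[0, 0] > 20.0  # dominated by the squared mean
        assert scm(x, center=True)[0, 0] < 3.0

    def test_rank_deficient_input_regularized_with_warning(self, rng):
        row = rng.normal(size=(1, 50))
        x = np.vstack([row, row, row])  # rank 1
        with pytest.warns(UserWarning, match="rank-deficient"):
            sigma = scm(x)
        assert np.linalg.eigvalsh(sigma)[0] > 0

    def test_single_column_rejected(self, rng):
        with pytest.raises(ValueError):
            scm(rng.normal(size=(3, 1)))


class TestRiemannianDistance:
    def test_identity_of_indiscernibles(self, rng):
        s = random_spd(rng, 5)
        assert riemannian_distance(s, s) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("a", [0.5, 2.0, 10.0])
    def test_commuting_closed_form(self, a):
        d = 12
        got = riemannian_distance(np.eye(d), a * np.eye(d))
        assert got == pytest.approx(np.sqrt(d) * abs(np.log(a)), rel=1e-12)

    def test_symmetry_and_congruence_invariance(self, rng):
        for _ in range(100):
            s1, s2 = random_spd(rng, 4), random_spd(rng, 4)
            a = rng.normal(size=(4, 4)) + 4 * np.eye(4)
            d12 = riemannian_distance(s1, s2)
            assert d12 == pytest.approx(riemannian_distance(s2, s1), rel=1e-10)
            assert riemannian_distance(a @ s1 @ a.T, a @ s2 @ a.T) == \
                pytest.approx(d12, rel=1e-8)

    def test_metric_axioms_on_sampled_triples(self, rng):
        for _ in range(200):
            s = [random_spd(rng, 3) for _ in range(3)]
            d01 = riemannian_distance(s[0], s[1])
            d12 = riemannian_distance(s[1], s[2])
            d02 = riemannian_distance(s[0], s[2])
            assert d01 >= 0
            assert d02 <= d01 + d12 + 1e-8

    def test_agrees_with_schur_route(self, rng):
        for _ in range(50):
            s1, s2 = random_spd(rng, 12), random_spd(rng, 12)
            ref = _ref_distance(s1, s2)
            assert riemannian_distance(s1, s2) == pytest.approx(ref, rel=1e-6)

    def test_non_spd_rejected(self, rng):
        with pytest.raises(ValueError):
            riemannian_distance(-np.eye(3), np.eye(3))
        with pytest.raises(ValueError):
            riemannian_distance(rng.normal(size=(3, 3)), np.eye(3))


class TestRiemannianMean:
    def test_mean_of_singleton(self, rng):
        s = random_spd(rng, 4)
        assert np.allclose(riemannian_mean([s]), s)

    def test_geometric_mean_of_commuting_pair(self):
        a, b = 2.0, 8.0
        mean = riemannian_mean([a * np.eye(5), b * np.eye(5)])
        assert np.allclose(mean, np.sqrt(a * b) * np.eye(5), atol=1e-8)

    def test_minimizes_frechet_objective(self, rng):
        mats = [random_spd(rng, 4) for _ in range(10)]
        mean = riemannian_mean(mats)

        def objective(s):
            return sum(riemannian_distance(s, m) ** 2 for m in mats)

        at_mean = objective(mean)
        assert at_mean <= objective(np.mean(mats, axis=0)) + 1e-9
        for m in mats:
            assert at_mean <= objective(m) + 1e-9

    def test_first_order_stationarity_schur_route(self, rng):
        """Gradient at the mean vanishes: sum of logs of the whitened set."""
        mats = [random_spd(rng, 6) for _ in range(8)]
        mean = riemannian_mean(mats, tol=1e-11)
        isqrt = sla.inv(sla.sqrtm(mean))
        grad = sum(sla.logm(isqrt @ m @ isqrt) for m in mats)
        assert np.linalg.norm(grad, "fro") < 1e-8

    def test_congruence_equivariance(self, rng):
        mats = [random_spd(rng, 4) for _ in range(6)]
        a = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        direct = riemannian_mean([a @ m @ a.T for m in mats], tol=1e-11)
        pushed = a @ riemannian_mean(mats, tol=1e-11) @ a.T
        assert np.allclose(direct, pushed, atol=1e-6 * np.abs(pushed).max())

    def test_nonconvergence_carries_iterate(self, rng):
        mats = [random_spd(rng, 4) for _ in range(5)]
        with pytest.raises(MeanConvergenceError) as err:
            riemannian_mean(mats, tol=1e-16, max_iter=1)
        assert err.value.iterate.shape == (4, 4)
        assert err.value.residual > 0


class TestTangentSpace:
    def test_zero_vector_at_base_point(self, rng):
        s = random_spd(rng, 5)
        assert np.allclose(tangent_project(s, s), 0.0, atol=1e-9)

    def test_dimension_is_upper_triangle(self):
        assert tangent_dim(12) == 78
        v = tangent_project(2 * np.eye(12), np.eye(12))
        assert v.shape == (78,)

    def test_norm_equals_distance_with_sqrt2_weighting(self, rng):
        for _ in range(100):
            s, base = random_spd(rng, 4), random_spd(rng, 4)
            v = tangent_project(s, base)
            assert np.linalg.norm(v) == pytest.approx(
                riemannian_distance(s, base), rel=1e-8
            )

    def test_agrees_with_schur_route(self, rng):
        for _ in range(50):
            s, base = random_spd(rng, 12), random_spd(rng, 12)
            ref = upper(_ref_tangent(s, base).real)
            assert np.allclose(tangent_project(s, base), ref, atol=1e-6)

    def test_batch_matches_single(self, rng):
        base = random_spd(rng, 6)
        mats = [random_spd(rng, 6) for _ in range(7)]
        batch = tangent_vectors(mats, base)
        for i, m in enumerate(mats):
            assert np.allclose(batch[i], tangent_project(m, base), atol=1e-10)

    def test_upper_without_weighting_is_plain_triangle(self, rng):
        m = rng.normal(size=(3, 3))
        m = m + m.T
        v = upper(m, sqrt2_offdiag=False)
        assert np.allclose(v, m[np.triu_indices(3)])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(min_value=0.01, max_value=100.0),
       st.integers(min_value=1, max_value=16))
def test_commuting_distance_closed_form_property(a, d):
    """delta(I_d, a I_d) = sqrt(d) |log a| for any scale and dimension."""
    assert riemannian_distance(np.eye(d), a * np.eye(d)) == \
        pytest.approx(np.sqrt(d) * abs(np.log(a)), rel=1e-9, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.integers(min_value=2, max_value=10))
def test_upper_vectorization_preserves_frobenius_norm(seed, d):
    """With sqrt(2) off-diagonal weighting the half-vectorization is an
    isometry from symmetric matrices to R^{d(d+1)/2}."""
    m = np.random.default_rng(seed).normal(size=(d, d))
    m = m + m.T
    assert np.linalg.norm(upper(m)) == pytest.approx(
        np.linalg.norm(m, "fro"), rel=1e-12
    )


class TestMDM:
    def _clouds(self, rng, n=30, spread=0.3):
        centers = [np.eye(4), np.diag([4.0, 2.0, 0.5, 0.25])]
        sigmas, labels = [], []
        for label, c in enumerate(centers):
            sq = sla.sqrtm(c)
            for _ in range(n):
                e = rng.normal(scale=spread, size=(4, 4))
                e = (e + e.T) / 2
                vals, vecs = np.linalg.eigh(e)
                sigmas.append(sq @ (vecs * np.exp(vals)) @ vecs.T @ sq)
                labels.append(bool(label))
        return np.array(sigmas), np.array(labels)

    def test_class_mean_classified_to_its_class(self, rng):
        sigmas, labels = self._clouds(rng)
        clf = MDM().fit(sigmas, labels)
        for c, mean in clf.means_.items():
            assert clf.predict([mean])[0] == c

    def test_equidistant_tie_breaks_to_negative_class(self):
        clf = MDM()
        clf.classes_ = np.array([False, True])
        clf.means_ = {False: 0.5 * np.eye(3), True: 2.0 * np.eye(3)}
        # identity is equidistant from both means under the log metric
        assert clf.predict([np.eye(3)])[0] == np.False_

    def test_unfitted_rejected(self):
        with pytest.raises(RuntimeError):
            MDM().predict([np.eye(2)])

    def test_accuracy_close_to_nearest_neighbor_oracle(self, rng):
        """On separable SPD clouds MDM stays within 5 points of brute-force
        1-NN under the same metric."""
        train_s, train_y = self._clouds(rng, n=40)
        test_s, test_y = self._clouds(rng, n=15)
        clf = MDM().fit(train_s, train_y)
        mdm_acc = (clf.predict(test_s) == test_y).mean()

        dists = np.array(
            [[riemannian_distance(t, s) for s in train_s] for t in test_s]
        )
        nn_acc = (train_y[np.argmin(dists, axis=1)] == test_y).mean()
        assert mdm_acc >= nn_acc - 0.05
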