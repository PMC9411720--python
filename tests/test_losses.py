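"""Loss family: l1, mutually projected l1, combined, divergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import srflow as sf
from srflow._nn.autograd import Tensor
from srflow.losses import (
    LossConfig,
    combined_loss_t,
    l1_loss_t,
    mp_l1_loss_t,
)

vec3 = st.tuples(*[st.floats(-2, 2, allow_nan=False) for _ in range(3)])


class TestL1:
    def test_zero_at_equality_and_unit_case(self, rng):
        v = rng.standard_normal((50, 3))
        assert sf.l1_loss(v, v) == 0.0
        assert sf.l1_loss([[1.0, 1.0, 1.0]], [[0.0, 0.0, 0.0]]) == 3.0

    def test_matches_brute_force_loop(self, rng):
        v = rng.standard_normal((100, 3))
        u = rng.standard_normal((100, 3))
        brute = sum(
            abs(v[i, c] - u[i, c]) for i in range(100) for c in range(3)
        ) / 100
        assert sf.l1_loss(v, u) == pytest.approx(brute, abs=1e-12)

    def test_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            sf.l1_loss(rng.standard_normal((4, 3)), rng.standard_normal((5, 3)))


class TestProjections:
    def test_J1_examples(self):
        u = (1.0, 0.0, 0.0)
        assert sf.projected_l1_J1((1, 5, 0), u) == pytest.approx(0.0)
        assert sf.projected_l1_J1((0, 1, 0), u) == pytest.approx(1.0)
        assert sf.projected_l1_J1((0.5, 0.5, 0), u) == pytest.approx(0.5)

    def test_J2_examples(self):
        u = (1.0, 0.0, 0.0)
        assert sf.projected_l1_J2(u, u) == pytest.approx(0.0)
        assert sf.projected_l1_J2((0.5, 0.5, 0), u) == pytest.approx(0.0, abs=1e-12)
        assert sf.projected_l1_J2((0, 1, 0), u) == pytest.approx(1.0)

    def test_J1_vanishes_on_plane(self, rng):
        """J1 = 0 exactly on the plane {v : u.v = ||u||^2}."""
        for _ in range(10):
            u = rng.uniform(-1, 1, 3)
            if np.linalg.norm(u) < 0.1:
                continue
            # v = u + any vector orthogonal to u
            w = rng.standard_normal(3)
            w -= w.dot(u) / u.dot(u) * u
            assert sf.projected_l1_J1(u + w, u) < 1e-9

    def test_J2_vanishes_on_sphere(self, rng):
        """J2 = 0 on the sphere centred at u/2 with radius ||u||/2."""
        for _ in range(10):
            u = rng.uniform(-1, 1, 3)
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            v = u / 2 + np.linalg.norm(u) / 2 * d
            if np.linalg.norm(v) < 1e-3:
                continue
            assert sf.projected_l1_J2(v, u) < 1e-9


class TestMutuallyProjected:
    def test_hand_examples(self):
        u = [[1.0, 0.0, 0.0]]
        assert sf.mp_l1_loss(u, u) == 0.0
        assert sf.mp_l1_loss([[0, 1, 0]], u) == pytest.approx(1.0)
        assert sf.mp_l1_loss([[2, 0, 0]], u) == pytest.approx(1.0)

    def test_direction_sensitivity(self):
        """Two predictions with the same l2 error size but different error
        direction get different mp-l1 penalties (l1 under permutation of
        the error components would not distinguish them)."""
        u = np.array([[1.0, 0.0, 0.0]])
        a = sf.mp_l1_loss([[1.0, 0.5, 0.0]], u)  # tangential error 0.5
        b = sf.mp_l1_loss([[1.5, 0.0, 0.0]], u)  # radial error 0.5
        assert a != pytest.approx(b)
        assert a < b  # errors orthogonal to u are penalized less

    def test_alpha_beta_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            LossConfig(alpha=0.7, beta=0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(v=vec3, u=vec3)
    def test_nonnegative(self, v, u):
        assert sf.mp_l1_loss([v], [u]) >= 0.0

    def test_unique_minimum_by_grid_search(self):
        """Brute-force minimization over a dense grid lands on v = u."""
        rng = np.random.default_rng(0)
        ax = np.linspace(-2, 2, 41)
        G = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
        cell = ax[1] - ax[0]
        for _ in range(5):
            u = rng.uniform(-1, 1, 3)
            dot = G @ u
            nu = np.linalg.norm(u)
            nv = np.linalg.norm(G, axis=1)
            j = 0.5 * np.abs(nu - dot / nu) + 0.5 * np.abs(
                nv - dot / np.maximum(nv, 1e-8)
            )
            vstar = G[np.argmin(j)]
            # zero sets are tangent at u: flat basin along the tangent
            # plane, so compare against one cell's diagonal extent
            assert np.linalg.norm(vstar - u) <= np.sqrt(3) * cell + 1e-12


class TestCombined:
    def test_zero_at_equality(self, rng):
        v = rng.standard_normal((20, 3))
        assert sf.combined_loss(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_weights_reduce_to_l1(self, rng):
        v, u = rng.standard_normal((30, 3)), rng.standard_normal((30, 3))
        cfg = LossConfig(lambda_l1=1.0, lambda_mp=0.0)
        assert sf.combined_loss(v, u, cfg) == sf.l1_loss(v, u)

    def test_defaults_are_sum_of_terms(self, rng):
        v, u = rng.standard_normal((30, 3)), rng.standard_normal((30, 3))
        total = sf.combined_loss(v, u)
        assert total == pytest.approx(
            sf.l1_loss(v, u) + sf.mp_l1_loss(v, u), abs=1e-12
        )


class TestDivergenceLoss:
    def test_zero_on_abc_and_constant(self, abc_field):
        assert sf.divergence_loss(abc_field) == 0.0
        const = sf.VelocityField(data=np.full((8, 8, 8, 3), 0.4))
        assert sf.divergence_loss(const) == 0.0

    def test_linear_field_oracle(self):
        """v = (x, 0, 0) on a unit grid has divergence 1 at every voxel
        (one-sided boundary differences are exact on linear fields)."""
        n = 8
        x = np.arange(float(n))
        data = np.zeros((n, n, n, 3))
        data[..., 0] = x[:, None, None]
        assert sf.divergence_loss(data) == pytest.approx(1.0)

    def test_too_small_field_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            sf.divergence_loss(np.zeros((2, 8, 8, 3)))


class TestAutodiffVariants:
    """The tensor losses agree with the NumPy ones and differentiate."""

    def _batchify(self, arr):
        # (n, 3) -> (1, 3, n, 1, 1) pseudo-volume
        return arr.T.reshape(1, 3, -1, 1, 1)

    def test_values_match_numpy(self, rng):
        v = rng.standard_normal((40, 3))
        u = rng.standard_normal((40, 3))
        vb, ub = self._batchify(v), self._batchify(u)
        assert l1_loss_t(Tensor(vb), ub).item() == pytest.approx(
            sf.l1_loss(v, u), rel=1e-12
        )
        assert mp_l1_loss_t(Tensor(vb), ub).item() == pytest.approx(
            sf.mp_l1_loss(v, u), rel=1e-10
        )
        assert combined_loss_t(Tensor(vb), ub).item() == pytest.approx(
            sf.combined_loss(v, u), rel=1e-10
        )

    def test_gradients_match_finite_differences(self, rng):
        v = rng.standard_normal((10, 3)) * 0.5
        u = rng.standard_normal((10, 3)) * 0.5
        vb, ub = self._batchify(v), self._batchify(u)
        t = Tensor(vb, requires_grad=True)
        loss = combined_loss_t(t, ub)
        loss.backward()
        g = t.grad.copy()
        eps = 1e-6
        for idx in [(0, 0, 0, 0, 0), (0, 1, 3, 0, 0), (0, 2, 9, 0, 0)]:
            pert = vb.copy()
            pert[idx] += eps
            hi = combined_loss_t(Tensor(pert), ub).item()
            pert[idx] -= 2 * eps
            lo = combined_loss_t(Tensor(pert), ub).item()
            num = (hi - lo) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_divergence_loss_t_matches_numpy(self, rng):
        data = rng.standard_normal((6, 6, 6, 3))
        t = Tensor(np.moveaxis(data, -1, 0)[None], requires_grad=True)
        from srflow.losses import divergence_loss_t

        val = divergence_loss_t(t, (1.0, 1.0, 1.0))
        assert val.item() == pytest.approx(sf.divergence_loss(data), rel=1e-12)
        val.backward()  # gradient exists and is finite
        assert np.all(np.isfinite(t.grad))
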