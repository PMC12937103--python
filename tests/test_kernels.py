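"""Kernel values, derivative blocks, symmetrization, Gram positivity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gpmlmm.geometry import Geometry, MMEnvironment
from gpmlmm.kernels import (
    KernelSpec,
    direct_kernel,
    env_kernel_blocks,
    internal_kernel_blocks,
    internal_pair_blocks,
    matern52,
    symmetrize,
)
from gpmlmm.kernels import KernelConfigError

from conftest import random_geometry


def _rand_env(rng, m=4, offset=6.0):
    return MMEnvironment(
        rng.normal(scale=3, size=(m, 3)) + offset, rng.normal(scale=0.25, size=m)
    )


class TestMatern:
    def test_value_at_zero_distance(self):
        assert matern52(0.0, 2.0) == 1.0

    def test_monotone_decay_to_zero(self):
        d = np.linspace(0, 50, 400)
        k = matern52(d, 1.5)
        assert np.all(np.diff(k) < 0)
        assert k[-1] < 1e-10
        assert np.all(k > 0) and np.all(k <= 1.0)

    def test_derivative_matches_finite_differences(self, rng):
        h = 1e-6
        for _ in range(10):
            d = rng.uniform(0.05, 5.0)
            lam = rng.uniform(0.3, 4.0)
            fd = (matern52(d + h, lam) - matern52(d - h, lam)) / (2 * h)
            from gpmlmm.kernels import _matern52_phi

            assert _matern52_phi(d, lam) * d == pytest.approx(fd, rel=1e-8, abs=1e-12)

    def test_invalid_lengthscale(self):
        with pytest.raises(KernelConfigError):
            matern52(1.0, 0.0)


class TestDirectKernel:
    def test_vacuum_side_gives_zero(self, rng):
        v = rng.normal(size=5)
        assert direct_kernel(v, np.zeros(5), theta=1.0) == 0.0

    def test_worked_arithmetic(self):
        assert direct_kernel([1.0, 0.0], [1.0, 0.0], theta=1.0) == pytest.approx(3.0)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=6), r.normal(size=6)
        assert direct_kernel(a, b) == pytest.approx(direct_kernel(b, a), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            direct_kernel([1.0], [1.0, 2.0])


SPEC = KernelSpec(1.0)
SPEC_SYM = KernelSpec(1.0, permutations=((0, 1, 2, 3), (0, 1, 3, 2)))


class TestInternalBlocks:
    def test_coincident_arguments(self, rng):
        g = random_geometry(rng)
        b = internal_kernel_blocks(g, g, SPEC)
        assert b.k == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(b.grad_i, -b.grad_j, atol=1e-12)

    def test_blocks_match_finite_differences(self, rng):
        h = 1e-5
        gi, gj = random_geometry(rng), random_geometry(rng)
        b = internal_kernel_blocks(gi, gj, SPEC)
        for g in range(12):
            d = np.zeros((4, 3))
            d.reshape(-1)[g] = h
            kp = internal_kernel_blocks(gi.with_coords(gi.coords + d), gj, SPEC)
            km = internal_kernel_blocks(gi.with_coords(gi.coords - d), gj, SPEC)
            assert b.grad_i[g] == pytest.approx((kp.k - km.k) / (2 * h), rel=1e-5)
            col = (kp.grad_j - km.grad_j) / (2 * h)
            np.testing.assert_allclose(b.hess[g], col, rtol=1e-5, atol=1e-10)

    def test_hessian_schwarz_symmetry(self, rng):
        gi, gj = random_geometry(rng), random_geometry(rng)
        b = internal_kernel_blocks(gi, gj, SPEC)
        bt = internal_kernel_blocks(gj, gi, SPEC)
        np.testing.assert_allclose(b.hess, bt.hess.T, atol=1e-10)


class TestEnvBlocks:
    def test_empty_second_environment_vacuum_limit(self, rng):
        gi, gj = random_geometry(rng), random_geometry(rng)
        envi = _rand_env(rng)
        b = env_kernel_blocks(gi, envi, gj, MMEnvironment.empty(), SPEC)
        assert b.k == 0.0
        assert np.all(b.grad_i == 0.0) and np.all(b.grad_j == 0.0)
        assert np.all(b.hess == 0.0)
        # the dV_j block survives: 2 theta V_i,a K_internal at V_j = 0
        ki = internal_kernel_blocks(gi, gj, SPEC).k
        from gpmlmm.descriptors import esp_descriptor

        vi = esp_descriptor(gi, envi).values
        np.testing.assert_allclose(b.dV_j, 2.0 * SPEC.theta * vi * ki, atol=1e-12)

    def test_blocks_match_finite_differences(self, rng):
        h = 1e-5
        gi = random_geometry(rng, n=3, symbols=("C", "O", "H"))
        gj = random_geometry(rng, n=3, symbols=("C", "O", "H"))
        spec = KernelSpec(1.0)
        envi, envj = _rand_env(rng), _rand_env(rng)
        b = env_kernel_blocks(gi, envi, gj, envj, spec)
        # QM coordinates, both sides, and the mixed Hessian
        for g in range(9):
            d = np.zeros(9)
            d[g] = h
            dp, dm = d.reshape(3, 3), -d.reshape(3, 3)
            kp = env_kernel_blocks(gi.with_coords(gi.coords + dp), envi, gj, envj, spec)
            km = env_kernel_blocks(gi.with_coords(gi.coords + dm), envi, gj, envj, spec)
            assert b.grad_i[g] == pytest.approx((kp.k - km.k) / (2 * h), rel=1e-5)
            kp = env_kernel_blocks(gi, envi, gj.with_coords(gj.coords + dp), envj, spec)
            km = env_kernel_blocks(gi, envi, gj.with_coords(gj.coords + dm), envj, spec)
            assert b.grad_j[g] == pytest.approx((kp.k - km.k) / (2 * h), rel=1e-5)
            np.testing.assert_allclose(
                b.hess[:, g], (kp.grad_i - km.grad_i) / (2 * h), rtol=1e-5, atol=1e-9
            )
        # MM coordinates and charges of the second argument
        for g in range(3 * envj.n_sites):
            d = np.zeros((envj.n_sites, 3))
            d.reshape(-1)[g] = h
            kp = env_kernel_blocks(
                gi, envi, gj, MMEnvironment(envj.coords + d, envj.charges), spec
            )
            km = env_kernel_blocks(
                gi, envi, gj, MMEnvironment(envj.coords - d, envj.charges), spec
            )
            assert b.mm_grad_j[g] == pytest.approx(
                (kp.k - km.k) / (2 * h), rel=1e-5, abs=1e-10
            )

    def test_argument_swap_transposes_blocks(self, rng):
        gi, gj = random_geometry(rng), random_geometry(rng)
        envi, envj = _rand_env(rng), _rand_env(rng, m=5)
        b = env_kernel_blocks(gi, envi, gj, envj, SPEC_SYM)
        bs = env_kernel_blocks(gj, envj, gi, envi, SPEC_SYM)
        assert b.k == pytest.approx(bs.k, abs=1e-10)
        np.testing.assert_allclose(b.grad_i, bs.grad_j, atol=1e-10)
        np.testing.assert_allclose(b.hess, bs.hess.T, atol=1e-10)
        np.testing.assert_allclose(b.dV_i, bs.dV_j, atol=1e-10)

    def test_atom_count_mismatch(self, rng):
        gi = random_geometry(rng, n=3, symbols=("C", "O", "H"))
        gj = random_geometry(rng)
        with pytest.raises(ValueError, match="atom count"):
            env_kernel_blocks(gi, _rand_env(rng), gj, _rand_env(rng), SPEC)


class TestSymmetrize:
    def test_identity_group_is_bitwise_identical(self, rng):
        gi, gj = random_geometry(rng), random_geometry(rng)
        fn = lambda a, b: internal_kernel_blocks(a, b, SPEC)
        wrapped = symmetrize(fn, ((0, 1, 2, 3),))
        b0, b1 = fn(gi, gj), wrapped(gi, gj)
        assert b0.k == b1.k
        np.testing.assert_array_equal(b0.hess, b1.hess)

    def test_value_invariant_under_group_permutation(self, rng):
        # methyl-type 3-cycle closure on a 5-atom fragment: S = 6
        symbols = ("C", "C", "H", "H", "H")
        perms = (
            (0, 1, 2, 3, 4),
            (0, 1, 3, 4, 2),
            (0, 1, 4, 2, 3),
            (0, 1, 3, 2, 4),
            (0, 1, 2, 4, 3),
            (0, 1, 4, 3, 2),
        )
        spec = KernelSpec(1.0, permutations=perms)
        gi = random_geometry(rng, n=5, symbols=symbols)
        gj = random_geometry(rng, n=5, symbols=symbols)
        ref = internal_kernel_blocks(gi, gj, spec).k
        for p in perms:
            assert internal_kernel_blocks(
                gi.permuted(np.array(p)), gj, spec
            ).k == pytest.approx(ref, abs=1e-12)
            assert internal_kernel_blocks(
                gi, gj.permuted(np.array(p)), spec
            ).k == pytest.approx(ref, abs=1e-12)

    def test_symmetrized_hessian_matches_finite_differences(self, rng):
        h = 1e-5
        gi, gj = random_geometry(rng), random_geometry(rng)
        b = internal_kernel_blocks(gi, gj, SPEC_SYM)
        for g in range(12):
            d = np.zeros((4, 3))
            d.reshape(-1)[g] = h
            kp = internal_kernel_blocks(gi, gj.with_coords(gj.coords + d), SPEC_SYM)
            km = internal_kernel_blocks(gi, gj.with_coords(gj.coords - d), SPEC_SYM)
            np.testing.assert_allclose(
                b.hess[:, g], (kp.grad_i - km.grad_i) / (2 * h), rtol=1e-5, atol=1e-9
            )

    def test_unlike_element_permutation_rejected(self, rng):
        g = random_geometry(rng)
        spec = KernelSpec(1.0, permutations=((1, 0, 2, 3),))
        with pytest.raises(KernelConfigError, match="unlike elements"):
            internal_kernel_blocks(g, g, spec)


class TestGramPositivity:
    def test_force_gram_is_spd_after_regularization(self, rng):
        from gpmlmm.kernels import featurize

        geoms = [random_geometry(rng) for _ in range(50)]
        feats = [featurize(g, None, np.arange(4)) for g in geoms]
        chi = np.stack([f.chi for f in feats])
        jchi = np.stack([f.jchi for f in feats])
        b = internal_pair_blocks(chi, jchi, chi, jchi, 1.0, hess=True)
        gram = b["h"].transpose(0, 2, 1, 3).reshape(50 * 12, 50 * 12)
        np.testing.assert_allclose(gram, gram.T, atol=1e-10)
        np.linalg.cholesky(gram + 1e-8 * np.eye(len(gram)))
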