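"""Tensor fitting and Westin scalar maps."""

import numpy as np
import pytest

from pseudoprog.dti import (
    DWIStack,
    DesignMatrixRankError,
    MissingBaselineError,
    TensorField,
    compute_scalar_maps,
    eigendecompose,
    fit_tensor,
    simulate_dwi,
    westin_indices,
)
from pseudoprog.synthetic import fibonacci_directions

from conftest import random_rotation

D_PLANTED = np.diag([2e-3, 1e-3, 1e-3])


def _stack_from_tensor(tensor, n_dirs=30, s0=1000.0, shape=(2, 2, 2)):
    bvals = np.concatenate([[0.0], np.full(n_dirs, 1000.0)])
    bvecs = np.vstack([[0, 0, 0], fibonacci_directions(n_dirs)])
    field = np.broadcast_to(tensor, shape + (3, 3))
    data = simulate_dwi(field, bvals, bvecs, s0)
    return DWIStack(data=data, bvals=bvals, bvecs=bvecs)


class TestFitTensor:
    def test_recovers_planted_tensor_exactly(self):
        stack = _stack_from_tensor(D_PLANTED)
        field = fit_tensor(stack)
        assert field.mask.all()
        fitted = field.as_matrices()[0, 0, 0]
        np.testing.assert_allclose(fitted, D_PLANTED, atol=1e-10)

    def test_rotated_tensor_recovered(self, rng):
        R = random_rotation(rng)
        D = R @ D_PLANTED @ R.T
        stack = _stack_from_tensor(D)
        fitted = fit_tensor(stack).as_matrices()[0, 0, 0]
        np.testing.assert_allclose(fitted, D, atol=1e-10)

    def test_all_volumes_equal_b0_gives_zero_tensor(self):
        bvals = np.concatenate([[0.0], np.full(30, 1000.0)])
        bvecs = np.vstack([[0, 0, 0], fibonacci_directions(30)])
        data = np.full((2, 2, 2, 31), 500.0)
        field = fit_tensor(DWIStack(data=data, bvals=bvals, bvecs=bvecs))
        np.testing.assert_allclose(field.components, 0.0, atol=1e-12)

    def test_zero_s0_voxel_excluded_from_mask(self):
        stack = _stack_from_tensor(D_PLANTED)
        stack.data[0, 0, 0, :] = 0.0
        field = fit_tensor(stack)
        assert not field.mask[0, 0, 0]
        assert field.mask[1, 1, 1]

    def test_too_few_directions_raises(self):
        bvals = np.array([0.0, 1000.0, 1000.0, 1000.0])
        bvecs = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        data = np.ones((1, 1, 1, 4))
        with pytest.raises(DesignMatrixRankError):
            fit_tensor(DWIStack(data=data, bvals=bvals, bvecs=bvecs))

    def test_missing_baseline_raises(self):
        bvals = np.full(30, 1000.0)
        bvecs = fibonacci_directions(30)
        with pytest.raises(MissingBaselineError):
            fit_tensor(DWIStack(data=np.ones((1, 1, 1, 30)), bvals=bvals, bvecs=bvecs))


class TestEigendecompose:
    def test_diagonal_case(self):
        comp = np.zeros((1, 1, 1, 6))
        comp[0, 0, 0, :3] = [2e-3, 1e-3, 1e-3]
        eig = eigendecompose(TensorField(comp, np.ones((1, 1, 1), bool)))
        np.testing.assert_allclose(eig.eigenvalues[0, 0, 0], [2e-3, 1e-3, 1e-3])

    def test_rotation_invariant_eigenvalues(self, rng):
        R = random_rotation(rng)
        D = R @ D_PLANTED @ R.T
        comp = np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])
        eig = eigendecompose(
            TensorField(comp.reshape(1, 1, 1, 6), np.ones((1, 1, 1), bool))
        )
        np.testing.assert_allclose(
            eig.eigenvalues[0, 0, 0], [2e-3, 1e-3, 1e-3], atol=1e-12
        )

    def test_negative_eigenvalue_clamped_and_counted(self):
        comp = np.zeros((1, 1, 1, 6))
        comp[0, 0, 0, :3] = [1e-3, 1e-3, -1e-5]
        eig = eigendecompose(TensorField(comp, np.ones((1, 1, 1), bool)))
        assert eig.n_clamped == 1
        assert eig.eigenvalues.min() == 0.0

    def test_nonfinite_voxel_invalidated_not_fatal(self):
        comp = np.zeros((2, 1, 1, 6))
        comp[0, 0, 0, 0] = np.nan
        comp[1, 0, 0, :3] = 1e-3
        eig = eigendecompose(TensorField(comp, np.ones((2, 1, 1), bool)))
        assert not eig.mask[0, 0, 0]
        assert eig.mask[1, 0, 0]


class TestScalarMaps:
    @pytest.mark.parametrize(
        "lams, expected",
        [
            # isotropic: FA=0, CL=0, CP=0, CS=1, MD=1e-3
            ((1e-3, 1e-3, 1e-3), {"MD": 1e-3, "FA": 0.0, "CL": 0.0, "CP": 0.0, "CS": 1.0}),
            # prolate (2,1,1)e-3: direct evaluation of the stated formulas
            (
                (2e-3, 1e-3, 1e-3),
                {
                    "MD": 4e-3 / 3,
                    "FA": np.sqrt(1 / 6),
                    "CL": 0.25,
                    "CP": 0.0,
                    "CS": 0.75,
                },
            ),
        ],
    )
    def test_known_eigenvalue_triples(self, lams, expected):
        md, fa, cl, cp, cs = westin_indices(np.array(lams)[None, :])
        got = {"MD": md[0], "FA": fa[0], "CL": cl[0], "CP": cp[0], "CS": cs[0]}
        for key, val in expected.items():
            assert got[key] == pytest.approx(val, abs=1e-12)

    def test_degenerate_zero_trace(self):
        md, fa, cl, cp, cs = westin_indices(np.zeros((1, 3)))
        assert md[0] == fa[0] == cl[0] == cp[0] == cs[0] == 0.0

    def test_partition_of_unity(self, rng):
        lams = np.sort(rng.uniform(0, 3e-3, size=(500, 3)))[:, ::-1]
        _, _, cl, cp, cs = westin_indices(lams)
        ok = lams.sum(axis=1) > 0
        np.testing.assert_allclose((cl + cp + cs)[ok], 1.0, atol=1e-12)

    def test_indices_rotation_invariant(self, rng):
        """FA/CL/CP/CS through the full fit are invariant under tensor rotation."""
        base = np.diag([2.2e-3, 0.9e-3, 0.4e-3])
        ref = None
        for _ in range(5):
            R = random_rotation(rng)
            stack = _stack_from_tensor(R @ base @ R.T, shape=(1, 1, 1))
            eig = eigendecompose(fit_tensor(stack))
            maps = compute_scalar_maps(eig)
            vals = np.array([maps[k].values[0, 0, 0] for k in ("FA", "CL", "CP", "CS")])
            if ref is None:
                ref = vals
            np.testing.assert_allclose(vals, ref, atol=1e-10)

    def test_zero_noise_round_trip(self):
        """Planted tensor -> DWI -> fit -> maps reproduces FA/CL to 1e-8."""
        lams = np.array([1.8e-3, 1.1e-3, 0.7e-3])
        stack = _stack_from_tensor(np.diag(lams))
        maps = compute_scalar_maps(eigendecompose(fit_tensor(stack)))
        md, fa, cl, *_ = westin_indices(lams[None, :])
        assert maps["FA"].values[0, 0, 0] == pytest.approx(fa[0], abs=1e-8)
        assert maps["CL"].values[0, 0, 0] == pytest.approx(cl[0], abs=1e-8)

    def test_md_error_decreases_with_rician_noise(self):
        """Fitted-MD error shrinks monotonically as Rician sigma -> 0."""
        lams = np.array([1.5e-3, 1.0e-3, 0.8e-3])
        true_md = lams.mean()
        bvals = np.concatenate([[0.0], np.full(30, 1000.0)])
        bvecs = np.vstack([[0, 0, 0], fibonacci_directions(30)])
        field = np.broadcast_to(np.diag(lams), (6, 6, 6, 3, 3))
        clean = simulate_dwi(field, bvals, bvecs, 1000.0)
        errors = []
        for sigma in (1e-2 * 1000, 1e-3 * 1000, 1e-4 * 1000):
            noise_rng = np.random.default_rng(7)
            noisy = np.sqrt(
                (clean + noise_rng.normal(0, sigma, clean.shape)) ** 2
                + noise_rng.normal(0, sigma, clean.shape) ** 2
            )
            stack = DWIStack(data=noisy, bvals=bvals, bvecs=bvecs)
            maps = compute_scalar_maps(eigendecompose(fit_tensor(stack)))
            errors.append(abs(np.median(maps["MD"].values) - true_md))
        assert errors[0] > errors[1] > errors[2]
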