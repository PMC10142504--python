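"""Diffusion-tensor fitting and Westin scalar maps.

Fits the single-tensor model S = S0 * exp(-b g'Dg) to a diffusion-weighted
stack by log-linear least squares and derives the rotationally invariant
scalar maps used downstream: mean diffusivity (MD), fractional anisotropy
(FA) and the trace-normalized Westin indices of linear (CL), planar (CP)
and spherical (CS) anisotropy.

With eigenvalues sorted l1 >= l2 >= l3 and trace T = l1+l2+l3:

    MD = T / 3
    FA = sqrt(3/2) * sqrt(sum (li - MD)^2) / sqrt(sum li^2)
    CL = (l1 - l2) / T
    CP = 2 (l2 - l3) / T
    CS = 3 l3 / T

so that CL + CP + CS = 1 wherever T > 0, and all four anisotropy indices
lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DWIStack",
    "TensorField",
    "EigenField",
    "ScalarMap",
    "fit_tensor",
    "eigendecompose",
    "compute_scalar_maps",
]


class DesignMatrixRankError(ValueError):
    """Fewer than six independent diffusion-encoding directions."""


class MissingBaselineError(ValueError):
    """No b=0 volume in the stack."""


@dataclass
class ScalarMap:
    """A named voxelwise scalar volume on a grid with a NIfTI affine."""

    name: str
    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")


@dataclass
class DWIStack:
    """4D diffusion-weighted acquisition plus encoding metadata.

    ``data`` is (x, y, z, n_volumes); ``bvals`` in s/mm^2; ``bvecs`` is
    (n_volumes, 3), unit norm for b > 0 and may be zero for b = 0.
    """

    data: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, volume)")
        if self.bvals.shape[0] != self.data.shape[3]:
            raise ValueError("one b-value per volume required")
        if self.bvecs.shape != (self.data.shape[3], 3):
            raise ValueError("bvecs must be (n_volumes, 3)")
        if np.any(self.data < 0):
            raise ValueError("DWI intensities must be >= 0")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("b>0 direction vectors must have unit norm")

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))


@dataclass
class TensorField:
    """Voxelwise symmetric diffusion tensor, lower-triangle storage.

    ``components`` is (x, y, z, 6) ordered (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    in mm^2/s; ``mask`` marks voxels where the fit is valid.
    """

    components: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def as_matrices(self) -> np.ndarray:
        """Return the (x, y, z, 3, 3) symmetric matrix representation."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.components, -1, 0)
        out = np.empty(self.components.shape[:-1] + (3, 3), dtype=float)
        out[..., 0, 0] = dxx
        out[..., 1, 1] = dyy
        out[..., 2, 2] = dzz
        out[..., 0, 1] = out[..., 1, 0] = dxy
        out[..., 0, 2] = out[..., 2, 0] = dxz
        out[..., 1, 2] = out[..., 2, 1] = dyz
        return out


@dataclass
class EigenField:
    """Sorted tensor eigenvalues (l1 >= l2 >= l3) and eigenvectors.

    ``eigenvalues`` is (x, y, z, 3) descending; negative values have been
    clamped to zero, with the number of affected voxels in ``n_clamped``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mask: np.ndarray
    n_clamped: int = 0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear design matrix: ln S = ln S0 - b g'Dg, row per volume.

    Columns: [1, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] coefficients.
    """
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )


def fit_tensor(dwi: DWIStack, mask: np.ndarray | None = None) -> TensorField:
    """Fit the diffusion tensor per voxel by unweighted log-linear least squares.

    Voxels whose b=0 signal is non-positive, or whose diffusion-weighted
    signal is non-positive anywhere, are excluded from the validity mask
    rather than raising.
    """
    if dwi.n_b0 == 0:
        raise MissingBaselineError("no b=0 volume in DWI stack")
    A = design_matrix(dwi.bvals, dwi.bvecs)
    if np.linalg.matrix_rank(A) < 7:
        raise DesignMatrixRankError(
            "need >= 6 non-collinear diffusion directions plus b=0"
        )
    shape = dwi.data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match DWI grid")

    signals = dwi.data[mask]  # (n_voxels, n_volumes)
    b0_mean = signals[:, dwi.bvals == 0].mean(axis=1)
    usable = (b0_mean > 0) & np.all(signals > 0, axis=1)

    components = np.zeros(shape + (6,), dtype=float)
    valid = np.zeros(shape, dtype=bool)
    if usable.any():
        logs = np.log(signals[usable]).T  # (n_volumes, n_usable)
        coef, *_ = np.linalg.lstsq(A, logs, rcond=None)
        vox = np.argwhere(mask)[usable]
        components[vox[:, 0], vox[:, 1], vox[:, 2]] = coef[1:].T
        valid[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return TensorField(components=components, mask=valid, affine=dwi.affine)


def eigendecompose(tensors: TensorField) -> EigenField:
    """Sorted eigendecomposition of the tensor field.

    Eigenvalues are returned descending; negatives are clamped to zero and
    counted. Voxels with non-finite components are invalidated, not fatal.
    """
    mats = tensors.as_matrices()
    finite = np.all(np.isfinite(tensors.components), axis=-1)
    valid = tensors.mask & finite
    mats = np.where(valid[..., None, None], mats, np.eye(3))

    evals, evecs = np.linalg.eigh(mats)  # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]

    negative = valid & np.any(evals < 0, axis=-1)
    n_clamped = int(np.count_nonzero(negative))
    evals = np.clip(evals, 0.0, None)
    evals[~valid] = 0.0
    return EigenField(
        eigenvalues=evals,
        eigenvectors=evecs,
        mask=valid,
        n_clamped=n_clamped,
        affine=tensors.affine,
    )


def westin_indices(evals: np.ndarray) -> tuple[np.ndarray, ...]:
    """(MD, FA, CL, CP, CS) from sorted eigenvalue triples, vectorized.

    Where the trace vanishes all anisotropy indices are defined as 0 and
    MD as 0 (the fully degenerate voxel).
    """
    l1, l2, l3 = evals[..., 0], evals[..., 1], evals[..., 2]
    trace = l1 + l2 + l3
    ok = trace > 0
    safe = np.where(ok, trace, 1.0)

    md = trace / 3.0
    dev = evals - md[..., None]
    sq = np.sqrt((evals**2).sum(axis=-1))
    sq = np.where(sq > 0, sq, 1.0)
    fa = np.sqrt(1.5) * np.sqrt((dev**2).sum(axis=-1)) / sq
    fa = np.where(ok, fa, 0.0)

    cl = np.where(ok, (l1 - l2) / safe, 0.0)
    cp = np.where(ok, 2.0 * (l2 - l3) / safe, 0.0)
    cs = np.where(ok, 3.0 * l3 / safe, 0.0)
    return md, fa, cl, cp, cs


def compute_scalar_maps(eig: EigenField) -> dict[str, ScalarMap]:
    """Compute the MD/FA/CL/CP/CS maps from an eigenvalue field."""
    md, fa, cl, cp, cs = westin_indices(eig.eigenvalues)
    out = {}
    for name, vals in [("MD", md), ("FA", fa), ("CL", cl), ("CP", cp), ("CS", cs)]:
        vals = np.where(eig.mask, vals, 0.0)
        out[name] = ScalarMap(name=name, values=vals, affine=eig.affine)
    return out


def simulate_dwi(
    tensors: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    s0: float | np.ndarray = 1000.0,
) -> np.ndarray:
    """Forward-simulate noiseless DWI signal S = S0 exp(-b g'Dg).

    ``tensors`` is (..., 3, 3); the result has a trailing volume axis.
    """
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    gdg = np.einsum("vi,...ij,vj->...v", g, tensors, g)
    s0 = np.asarray(s0, dtype=float)
    if s0.ndim:
        s0 = s0[..., None]
    return s0 * np.exp(-b * gdg)
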