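"""Synthetic study data: feature cohorts and voxel-level phantom cases.

The source cohort (56 post-chemoradiation glioblastoma patients with new
enhancing lesions) is not publicly deposited, so everything downstream is
exercised on two synthetic stand-ins:

* `generate_cohort_features` draws per-case (FA, CL, rCBVmax) feature
  vectors from group-specific truncated normals whose means and SDs are
  the published group statistics (TP+mixed n=37: FA 0.14+-0.03,
  CL 0.05+-0.03, rCBVmax 4.09+-1.85; PsP n=19: 0.11+-0.02, 0.04+-0.01,
  2.49+-0.97). Features are independent by default because only marginals
  were published; a correlation matrix can be supplied to explore joint
  structure.

* `generate_phantom_case` builds a full voxel-level case - DWI stack
  forward-simulated from a planted tensor field (b=0/1000, 30 directions),
  a DSC time series with planted gamma-variate bolus kinetics (45
  timepoints at TR=2 s, TE=45 ms) and a pre/post-contrast T1 pair with a
  planted enhancing lesion - such that running the full pipeline recovers
  the planted (FA, CL, rCBVmax) triple.

The phantom geometry is a spherical lesion inside an ellipsoidal brain:
only ROI summary statistics feed the model, so geometric realism is not
needed. Planted tensors are uniform per tissue, with eigenvalues solved
exactly from the target (MD, FA, CL) triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dsc import DSCSeries, gamma_variate
from .dti import DWIStack, ScalarMap, simulate_dwi, westin_indices
from .model import PSP, TP_MIXED

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "generate_cohort_features",
    "PhantomCase",
    "generate_phantom_case",
    "default_phantom_sweep",
    "eigenvalues_from_indices",
    "fibonacci_directions",
]

FEATURES = ("fa_median", "cl_median", "rcbv_max")


@dataclass(frozen=True)
class GroupSpec:
    """Marginal feature distribution of one diagnostic group."""

    label: str
    n: int
    mean: tuple[float, float, float]  # (FA, CL, rCBVmax)
    sd: tuple[float, float, float]


@dataclass
class CohortSpec:
    """Sampling specification for a synthetic feature cohort.

    Defaults are the published group statistics; features are truncated
    to their physical ranges (FA, CL in [0,1]; rCBVmax >= 0).
    """

    groups: tuple[GroupSpec, GroupSpec] = (
        GroupSpec(TP_MIXED, 37, (0.14, 0.05, 4.09), (0.03, 0.03, 1.85)),
        GroupSpec(PSP, 19, (0.11, 0.04, 2.49), (0.02, 0.01, 0.97)),
    )
    correlation: np.ndarray = field(default_factory=lambda: np.eye(3))
    lower: tuple[float, float, float] = (0.0, 0.0, 0.0)
    upper: tuple[float, float, float] = (1.0, 1.0, np.inf)

    def validate(self) -> None:
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ValueError("correlation must be a symmetric 3x3 matrix")
        if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        for g in self.groups:
            if g.n < 1:
                raise ValueError("each group needs n >= 1")
            if any(s <= 0 for s in g.sd):
                raise ValueError("SDs must be positive")


def _match_truncnorm_params(
    target_mean: float, target_sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Underlying normal (mu, sigma) whose [lo, hi]-truncation has the
    target mean and SD (so the synthetic cohort reproduces the published
    group moments, not just the parameters of an untruncated normal).

    When the bounds are > 5 sigma away the correction is negligible and
    the targets are returned unchanged.
    """
    from scipy.optimize import fsolve
    from scipy.stats import truncnorm

    if (target_mean - lo) > 5 * target_sd and (hi - target_mean) > 5 * target_sd:
        return target_mean, target_sd

    def eqs(params):
        mu, log_s = params
        s = np.exp(log_s)
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [m - target_mean, np.sqrt(v) - target_sd]

    sol, info, ok, _ = fsolve(
        eqs, [target_mean, np.log(target_sd)], full_output=True
    )
    if ok != 1 or np.max(np.abs(info["fvec"])) > 1e-8 * max(target_sd, 1e-12):
        raise ValueError("infeasible truncation: cannot match target moments")
    return float(sol[0]), float(np.exp(sol[1]))


def _truncated_mvn(
    rng: np.random.Generator,
    n: int,
    mean: np.ndarray,
    sd: np.ndarray,
    corr: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Rejection sampling of a truncated multivariate normal whose
    post-truncation marginal moments match ``mean`` and ``sd``."""
    adj = [
        _match_truncnorm_params(m, s, lo, hi)
        for m, s, lo, hi in zip(mean, sd, lower, upper)
    ]
    mean = np.array([a[0] for a in adj])
    sd = np.array([a[1] for a in adj])
    cov = corr * np.outer(sd, sd)
    out = np.empty((0, 3))
    attempts = 0
    while out.shape[0] < n:
        draw = rng.multivariate_normal(mean, cov, size=max(2 * n, 64))
        keep = np.all((draw >= lower) & (draw <= upper), axis=1)
        out = np.vstack([out, draw[keep]])
        attempts += 1
        if attempts > 1000:
            raise ValueError("infeasible truncation: acceptance mass too small")
    return out[:n]


def generate_cohort_features(
    spec: CohortSpec | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw a synthetic feature cohort, one row per case.

    Columns: case_id, fa_median, cl_median, rcbv_max, truth_label.
    Deterministic given the seed.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for group in spec.groups:
        draws = _truncated_mvn(
            rng,
            group.n,
            np.asarray(group.mean, float),
            np.asarray(group.sd, float),
            np.asarray(spec.correlation, float),
            np.asarray(spec.lower, float),
            np.asarray(spec.upper, float),
        )
        for row in draws:
            rows.append((row[0], row[1], row[2], group.label))
    df = pd.DataFrame(rows, columns=[*FEATURES, "truth_label"])
    df.insert(0, "case_id", [f"case{i:03d}" for i in range(len(df))])
    return df


# --------------------------------------------------------------------------
# voxel-level phantoms


def eigenvalues_from_indices(md: float, fa: float, cl: float) -> np.ndarray:
    """Solve sorted eigenvalues (l1, l2, l3) from target (MD, FA, CL).

    With trace T = 3*MD and l1 = l2 + CL*T fixed by CL, l2 is the single
    remaining degree of freedom; FA is monotone in l2 on the admissible
    interval [T(1-CL)/3, T(1-CL)/2] (prolate limit to l3=0), so the root
    is found by bisection. Raises when the (FA, CL) pair is infeasible
    (FA below the prolate minimum for that CL).
    """
    T = 3.0 * md

    def eigs(l2: float) -> np.ndarray:
        l1 = l2 + cl * T
        l3 = T - l1 - l2
        return np.array([l1, l2, l3])

    def fa_of(l2: float) -> float:
        return float(westin_indices(eigs(l2)[None, :])[1][0])

    lo = T * (1.0 - cl) / 3.0
    hi = T * (1.0 - cl) / 2.0 - 1e-12 * T
    f_lo, f_hi = fa_of(lo), fa_of(hi)
    tol = 1e-9
    if fa <= f_lo + tol:
        if fa < f_lo - tol:
            raise ValueError(
                f"(FA={fa}, CL={cl}) infeasible: FA must lie in "
                f"[{f_lo:.4f}, {f_hi:.4f}] for this CL"
            )
        l2 = lo
    elif fa >= f_hi - tol:
        if fa > f_hi + tol:
            raise ValueError(
                f"(FA={fa}, CL={cl}) infeasible: FA must lie in "
                f"[{f_lo:.4f}, {f_hi:.4f}] for this CL"
            )
        l2 = hi
    else:
        l2 = brentq(lambda x: fa_of(x) - fa, lo, hi, xtol=1e-16)
    out = eigs(l2)
    assert out[0] >= out[1] >= out[2] >= -1e-15
    return np.clip(out, 0.0, None)


def fibonacci_directions(n: int = 30) -> np.ndarray:
    """n roughly uniform unit vectors on the upper hemisphere
    (deterministic; hemispheric because the diffusion signal is antipodally
    symmetric, so near-antipodal pairs would duplicate directions)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    dirs = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass
class PhantomCase:
    """Planted parameters of one voxel-level phantom case.

    The planted (fa, cl, rcbv_max) triple is the ground truth the full
    pipeline must recover; `rcbv_max` is planted as the uniform
    lesion-to-NAWM CBV ratio (uniform lesion => median = 90th percentile).
    """

    fa: float = 0.14
    cl: float = 0.05
    rcbv_max: float = 4.09
    md: float = 1.0e-3  # mm^2/s, planted lesion mean diffusivity
    shape: tuple[int, int, int] = (32, 32, 16)
    lesion_center: tuple[float, float, float] = (22.0, 16.0, 8.0)
    lesion_radius: float = 3.2
    nawm_md: float = 0.75e-3
    nawm_fa: float = 0.45
    nawm_cl: float = 0.15
    enhancement: float = 0.5
    dwi_noise_sigma: float = 0.0  # Rician, in signal units
    dsc_noise_sigma: float = 0.0  # Gaussian, in signal units
    seed: int = 0
    b_value: float = 1000.0
    n_directions: int = 30
    tr: float = 2.0
    te: float = 0.045
    n_timepoints: int = 45
    # shared bolus kinetics; lesion amplitude scales with rcbv_max
    bolus_t0: float = 20.0
    bolus_alpha: float = 3.0
    bolus_beta: float = 1.5
    nawm_k: float = 2.0

    def validate(self) -> None:
        if self.dwi_noise_sigma < 0 or self.dsc_noise_sigma < 0:
            raise ValueError("noise level must be >= 0")
        c = np.asarray(self.lesion_center)
        semi = self._brain_semiaxes()
        ctr = self._brain_center()
        if np.sum(((c - ctr) / (semi - self.lesion_radius)) ** 2) > 1.0:
            raise ValueError("lesion not fully inside the brain ellipsoid")

    def _brain_center(self) -> np.ndarray:
        return (np.asarray(self.shape, float) - 1.0) / 2.0

    def _brain_semiaxes(self) -> np.ndarray:
        return np.asarray(self.shape, float) / 2.0 - 1.0

    def brain_mask(self) -> np.ndarray:
        grids = np.ogrid[[slice(0, n) for n in self.shape]]
        ctr, semi = self._brain_center(), self._brain_semiaxes()
        return sum(((g - c) / s) ** 2 for g, c, s in zip(grids, ctr, semi)) <= 1.0

    def lesion_mask(self) -> np.ndarray:
        grids = np.ogrid[[slice(0, n) for n in self.shape]]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, self.lesion_center))
        return d2 <= self.lesion_radius**2


def _tensor_from(md: float, fa: float, cl: float) -> np.ndarray:
    return np.diag(eigenvalues_from_indices(md, fa, cl))


def generate_phantom_case(case: PhantomCase | None = None) -> dict:
    """Build the full synthetic case: DWI, DSC, T1 pair and truth record.

    Deterministic given ``case.seed``; zero noise by default.
    """
    case = case or PhantomCase()
    case.validate()
    rng = np.random.default_rng(case.seed)
    brain = case.brain_mask()
    lesion = case.lesion_mask() & brain

    # --- planted tensor field
    tensors = np.zeros(case.shape + (3, 3))
    tensors[brain] = _tensor_from(case.nawm_md, case.nawm_fa, case.nawm_cl)
    tensors[lesion] = _tensor_from(case.md, case.fa, case.cl)

    bvals = np.concatenate([[0.0], np.full(case.n_directions, case.b_value)])
    bvecs = np.vstack([[0.0, 0.0, 0.0], fibonacci_directions(case.n_directions)])
    s0 = np.where(brain, 1000.0, 0.0)
    dwi_data = simulate_dwi(tensors, bvals, bvecs, s0)
    if case.dwi_noise_sigma > 0:
        sig = case.dwi_noise_sigma
        dwi_data = np.sqrt(
            (dwi_data + rng.normal(0, sig, dwi_data.shape)) ** 2
            + rng.normal(0, sig, dwi_data.shape) ** 2
        )
    dwi = DWIStack(data=dwi_data, bvals=bvals, bvecs=bvecs)

    # --- planted bolus kinetics: same shape everywhere, amplitude per tissue
    times = np.arange(case.n_timepoints) * case.tr
    shape_curve = gamma_variate(
        times, 1.0, case.bolus_alpha, case.bolus_beta, case.bolus_t0
    )
    k_map = np.zeros(case.shape)
    k_map[brain] = case.nawm_k
    k_map[lesion] = case.nawm_k * case.rcbv_max
    conc = k_map[..., None] * shape_curve
    dsc_s0 = np.where(brain, 600.0, 0.0)
    dsc_data = dsc_s0[..., None] * np.exp(-case.te * conc)
    dsc_data[~brain] = 0.0
    if case.dsc_noise_sigma > 0:
        dsc_data = np.clip(
            dsc_data + rng.normal(0, case.dsc_noise_sigma, dsc_data.shape), 0.0, None
        )
    dsc = DSCSeries(data=dsc_data, tr=case.tr, te=case.te)

    # --- T1 pair: planted enhancement in the lesion plus a faint
    # deterministic ripple so NAWM enhancement statistics are non-degenerate
    pre = np.where(brain, 1000.0, 0.0)
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in case.shape], indexing="ij")
    ripple = 0.005 * np.sin(ii * 1.7 + jj * 0.9 + kk * 1.3)
    e = np.where(brain, ripple, 0.0)
    e[lesion] = case.enhancement
    post = pre * (1.0 + e)

    seed_voxel = tuple(int(round(c)) for c in case.lesion_center)
    return {
        "dwi": dwi,
        "dsc": dsc,
        "pre_t1": ScalarMap("pre_t1", pre),
        "post_t1": ScalarMap("post_t1", post),
        "brain_mask": brain,
        "lesion_mask": lesion,
        "seed_voxel": seed_voxel,
        "truth": {
            "fa": case.fa,
            "cl": case.cl,
            "rcbv_max": case.rcbv_max,
            "md": case.md,
            "seed": case.seed,
        },
        "case": case,
    }


def default_phantom_sweep(n: int = 20) -> list[PhantomCase]:
    """n zero-noise phantoms spanning FA 0.08-0.20, CL 0.02-0.08 and
    rCBVmax 1.5-8 (CL capped below the prolate feasibility bound for its
    FA, which rules out high-CL/low-FA combinations no tensor attains)."""
    fas = np.linspace(0.08, 0.20, n)
    cls_ = np.minimum(np.linspace(0.02, 0.08, n), fas / 1.8)
    rcbvs = np.linspace(1.5, 8.0, n)
    return [
        PhantomCase(fa=float(f), cl=float(c), rcbv_max=float(r), seed=i)
        for i, (f, c, r) in enumerate(zip(fas, cls_, rcbvs))
    ]
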