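"""DSC perfusion: signal to dR2*, gamma-variate bolus fit, CBV and rCBV.

Dynamic susceptibility contrast (DSC) perfusion converts the T2*-weighted
signal drop during a gadolinium bolus into the relaxation-rate change

    dR2*(t) = -ln(S(t) / S0) / TE,

with S0 the mean pre-bolus baseline signal, fits the canonical first-pass
gamma-variate model

    C(t) = K (t - t0)^alpha exp(-(t - t0) / beta),   t > t0,

to the truncated first pass (bolus arrival up to the first post-peak sample
below half peak, which excludes the recirculation/leakage tail), and takes
cerebral blood volume as the closed-form integral of the fitted curve,

    CBV = K beta^(alpha+1) Gamma(alpha+1)    (arbitrary units).

CBV only ever leaves this module as rCBV: the ratio to the mean CBV of a
contralateral normal-appearing white-matter reference region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn

__all__ = [
    "DSCSeries",
    "ConcentrationSeries",
    "GammaVariateFit",
    "gamma_variate",
    "signal_to_deltaR2star",
    "detect_bolus_arrival",
    "fit_gamma_variate",
    "compute_cbv",
    "cbv_map",
    "normalize_rcbv",
]

DEFAULT_BASELINE = (0, 8)  # first eight timepoints, pre-bolus
DELTA_R2_CEILING = 100.0  # s^-1 cap for voxels whose signal hits zero


class NormalizationError(ValueError):
    """Reference ROI empty or with non-positive mean CBV."""


@dataclass
class DSCSeries:
    """4D DSC-PWI acquisition: (x, y, z, t) with TR and TE in seconds."""

    data: np.ndarray
    tr: float = 2.0
    te: float = 0.045
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DSC data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 10:
            raise ValueError("need at least 10 timepoints")
        if self.te <= 0:
            raise ValueError("TE must be positive")
        if np.any(self.data < 0):
            raise ValueError("DSC intensities must be >= 0")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.tr


@dataclass
class ConcentrationSeries:
    """Voxelwise dR2*(t) in s^-1 with the baseline window that defined S0."""

    delta_r2s: np.ndarray
    times: np.ndarray
    baseline: tuple[int, int]
    mask: np.ndarray
    capped: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


@dataclass
class GammaVariateFit:
    """Fitted first-pass parameters; K=0 / converged=False flags no bolus."""

    K: float
    alpha: float
    beta: float
    t0: float
    rss: float
    converged: bool


def gamma_variate(
    t: np.ndarray, K: float, alpha: float, beta: float, t0: float
) -> np.ndarray:
    """Evaluate K (t-t0)^alpha exp(-(t-t0)/beta), zero for t <= t0."""
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(dt)
    pos = dt > 0
    out[pos] = K * dt[pos] ** alpha * np.exp(-dt[pos] / beta)
    return out


def signal_to_deltaR2star(
    series: DSCSeries,
    baseline: tuple[int, int] = DEFAULT_BASELINE,
    mask: np.ndarray | None = None,
    ceiling: float = DELTA_R2_CEILING,
) -> ConcentrationSeries:
    """Convert the DSC signal to dR2*(t) = -ln(S/S0)/TE per voxel.

    S0 is the mean over the ``baseline`` half-open index window. Voxels
    with S0 <= 0 are invalidated; samples where S(t) = 0 are capped at
    ``ceiling`` and flagged in ``capped``.
    """
    lo, hi = baseline
    if not (0 <= lo < hi <= series.n_timepoints):
        raise ValueError("baseline window empty or out of range")
    shape = series.data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    s0 = series.data[..., lo:hi].mean(axis=-1)
    valid = mask & (s0 > 0)
    safe_s0 = np.where(valid, s0, 1.0)

    with np.errstate(divide="ignore"):
        ratio = series.data / safe_s0[..., None]
        dr2s = -np.log(ratio) / series.te
    capped = valid[..., None] & ~np.isfinite(dr2s)
    dr2s = np.where(capped, ceiling, dr2s)
    dr2s = np.minimum(dr2s, ceiling)
    dr2s[~valid] = 0.0
    return ConcentrationSeries(
        delta_r2s=dr2s,
        times=series.times,
        baseline=baseline,
        mask=valid,
        capped=np.any(capped, axis=-1),
        affine=series.affine,
    )


def detect_bolus_arrival(
    conc: ConcentrationSeries, n_sigma: float = 3.0
) -> int:
    """Global bolus-arrival index from the mean in-mask dR2* curve.

    First timepoint after the baseline window where the whole-brain mean
    curve exceeds baseline mean + n_sigma * baseline SD (with a small
    absolute floor so a noiseless baseline still yields a threshold).
    """
    mean_curve = conc.delta_r2s[conc.mask].mean(axis=0)
    lo, hi = conc.baseline
    base = mean_curve[lo:hi]
    thresh = base.mean() + max(n_sigma * base.std(), 1e-9)
    above = np.nonzero(mean_curve[hi:] > thresh)[0]
    if above.size == 0:
        return conc.delta_r2s.shape[-1]  # no bolus detected
    return hi + int(above[0])


def _first_pass_window(
    curve: np.ndarray, arrival: int
) -> tuple[int, int]:
    """[start, stop) window from bolus arrival to the first post-peak sample
    below 50% of peak; excludes recirculation and leakage tail."""
    peak = int(np.argmax(curve[arrival:])) + arrival
    half = 0.5 * curve[peak]
    stop = curve.size
    for i in range(peak + 1, curve.size):
        if curve[i] < half:
            stop = i + 1  # include the first sub-half sample
            break
    start = arrival - 1 if arrival > 0 else 0
    return start, stop


def fit_gamma_variate(
    curve: np.ndarray,
    times: np.ndarray,
    baseline: tuple[int, int] = DEFAULT_BASELINE,
    peak_snr: float = 3.0,
) -> GammaVariateFit:
    """Fit the gamma-variate model to one dR2* curve.

    Initialization comes from the log-linearized form
    ln C = ln K + alpha ln(t-t0) - (t-t0)/beta fitted over the truncated
    first pass, refined by bounded nonlinear least squares on that window.
    A curve with no detectable positive peak (max <= peak_snr * baseline SD,
    with an absolute floor) returns a non-converged zero fit.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    lo, hi = baseline
    base = curve[lo:hi]
    floor = max(peak_snr * base.std(), 1e-12)
    post = curve[hi:]
    if post.size == 0 or post.max() <= max(base.mean() + floor, 1e-12):
        return GammaVariateFit(0.0, 1.0, 1.0, 0.0, float(np.sum(curve**2)), False)

    above = np.nonzero(post > base.mean() + floor)[0]
    arrival = hi + int(above[0])
    start, stop = _first_pass_window(curve, arrival)
    tw, cw = times[start:stop], curve[start:stop]

    # log-linear initialization on strictly positive samples
    t0_init = times[arrival - 1] if arrival > 0 else times[0]
    pos = (cw > 0) & (tw > t0_init)
    if pos.sum() >= 3:
        dt = tw[pos] - t0_init
        A = np.column_stack([np.ones_like(dt), np.log(dt), -dt])
        coef, *_ = np.linalg.lstsq(A, np.log(cw[pos]), rcond=None)
        k0 = float(np.exp(coef[0]))
        a0 = float(max(coef[1], 0.1))
        b0 = float(1.0 / coef[2]) if coef[2] > 0 else (tw[-1] - t0_init) / 4.0
        b0 = max(b0, 1e-3)
    else:
        k0, a0, b0 = max(cw.max(), 1e-6), 2.0, (tw[-1] - t0_init) / 4.0

    t_peak = times[int(np.argmax(curve))]

    def residuals(p):
        return gamma_variate(tw, *p) - cw

    res = least_squares(
        residuals,
        x0=[k0, a0, b0, max(t0_init, 0.0)],
        bounds=([0.0, 1e-3, 1e-3, 0.0], [np.inf, 50.0, np.inf, t_peak]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    K, alpha, beta, t0 = (float(v) for v in res.x)
    return GammaVariateFit(
        K=K,
        alpha=alpha,
        beta=beta,
        t0=t0,
        rss=float(np.sum(res.fun**2)),
        converged=bool(res.success),
    )


def compute_cbv(
    fit: GammaVariateFit,
    curve: np.ndarray | None = None,
    times: np.ndarray | None = None,
    fallback: bool = True,
) -> float:
    """CBV (arbitrary units) as the gamma-variate integral.

    Converged fit: closed form K beta^(alpha+1) Gamma(alpha+1). A
    non-converged fit falls back (if enabled and a curve is supplied) to
    the trapezoidal integral of the measured curve clipped at zero;
    otherwise NaN marks the missing value.
    """
    if fit.converged:
        return fit.K * fit.beta ** (fit.alpha + 1.0) * gamma_fn(fit.alpha + 1.0)
    if fit.K == 0.0:
        return 0.0
    if fallback and curve is not None and times is not None:
        return float(np.trapezoid(np.clip(curve, 0.0, None), times))
    return float("nan")


def cbv_map(
    conc: ConcentrationSeries,
    mask: np.ndarray | None = None,
    peak_snr: float = 3.0,
) -> np.ndarray:
    """Voxelwise CBV over ``mask`` (default: the valid concentration mask).

    Voxels where the gamma fit finds no bolus get CBV 0.
    """
    mask = conc.mask if mask is None else (np.asarray(mask, bool) & conc.mask)
    out = np.zeros(conc.delta_r2s.shape[:3], dtype=float)
    for idx in np.argwhere(mask):
        curve = conc.delta_r2s[tuple(idx)]
        fit = fit_gamma_variate(curve, conc.times, conc.baseline, peak_snr)
        out[tuple(idx)] = compute_cbv(fit, curve, conc.times)
    return out


def normalize_rcbv(cbv: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """rCBV = CBV / mean(CBV over the contralateral NAWM reference ROI)."""
    reference = np.asarray(reference, dtype=bool)
    if not reference.any():
        raise NormalizationError("reference ROI is empty")
    ref_mean = float(np.asarray(cbv)[reference].mean())
    if ref_mean <= 0:
        raise NormalizationError("reference ROI mean CBV is not positive")
    return np.asarray(cbv, dtype=float) / ref_mean
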