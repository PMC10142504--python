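"""Per-lesion feature extraction from scalar maps and a lesion mask.

The model's inputs are summary statistics over the contrast-enhancing
region: medians of MD, FA, CL, CP, CS and rCBV, plus rCBVmax defined as
the 90th percentile of the in-lesion rCBV distribution (linear
interpolation between order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["LesionFeatures", "extract_features"]


class MissingMapError(KeyError):
    """A required scalar map was not supplied."""


@dataclass
class LesionFeatures:
    """The per-lesion feature vector; (fa_median, cl_median, rcbv_max)
    feed the predictive-probability model."""

    fa_median: float
    cl_median: float
    rcbv_max: float
    md_median: float = float("nan")
    cp_median: float = float("nan")
    cs_median: float = float("nan")
    rcbv_median: float = float("nan")
    n_voxels: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def _masked_values(arr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = np.asarray(arr, dtype=float)[mask]
    return vals[np.isfinite(vals)]


def extract_features(
    maps: dict[str, np.ndarray],
    mask: np.ndarray,
    rcbvmax_mode: str = "p90",
) -> LesionFeatures:
    """Reduce scalar maps over the lesion mask to one feature row.

    ``maps`` must contain 'FA', 'CL' and 'rCBV' (MD/CP/CS optional; their
    medians are NaN when absent). Voxels non-finite in one map are dropped
    from that map's statistic only. ``rcbvmax_mode`` selects the reading of
    the maximum-perfusion summary: 'p90' (90th percentile, default) or
    'top10mean' (mean of the top decile).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lesion mask")
    for required in ("FA", "CL", "rCBV"):
        if required not in maps:
            raise MissingMapError(f"required map missing: {required}")
    if rcbvmax_mode not in ("p90", "top10mean"):
        raise ValueError("rcbvmax_mode must be 'p90' or 'top10mean'")

    def med(name: str) -> float:
        if name not in maps:
            return float("nan")
        vals = _masked_values(maps[name], mask)
        return float(np.median(vals)) if vals.size else float("nan")

    rcbv = _masked_values(maps["rCBV"], mask)
    if rcbvmax_mode == "p90":
        rcbv_max = float(np.percentile(rcbv, 90.0))  # linear interpolation
    else:
        p90 = np.percentile(rcbv, 90.0)
        rcbv_max = float(rcbv[rcbv >= p90].mean())

    return LesionFeatures(
        fa_median=med("FA"),
        cl_median=med("CL"),
        rcbv_max=rcbv_max,
        md_median=med("MD"),
        cp_median=med("CP"),
        cs_median=med("CS"),
        rcbv_median=med("rCBV"),
        n_voxels=int(mask.sum()),
    )
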