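"""Case- and cohort-level drivers composing the full analysis.

`run_case` takes one spatially aligned case (DWI + DSC + pre/post T1 +
lesion seed) through tensor fitting, perfusion, segmentation, feature
extraction and the predictive-probability model. `run_cohort` applies the
model to a feature table (one row per case) and computes the cohort
validation statistics: confusion summary, Mann-Whitney group comparisons,
point-biserial concordance, ROC/AUC and leave-one-out cross-validation.

The statistical layer is reachable directly from a features-only table so
it can be exercised without any image processing; both entry points
produce identical downstream results by construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import dsc as dscmod
from . import dti as dtimod
from .features import LesionFeatures, extract_features
from .model import (
    PSP,
    TP_MIXED,
    ModelCoefficients,
    ProgressionClassifier,
    classify,
    predictive_probability,
    summarize_cohort,
)
from .roi import mirror_contralateral, segment_enhancing, sphere_roi
from .stats import concordance_pearson, ks_normality_gate, loocv, mann_whitney, roc_auc
from .synthetic import FEATURES

logger = logging.getLogger("pseudoprog")

__all__ = ["PipelineConfig", "CaseResult", "run_case", "run_cohort", "validate_cohort"]


@dataclass
class PipelineConfig:
    """Tunables of the per-case pipeline and decision thresholds."""

    k_sigma: float = 3.0  # segmentation threshold multiplier
    rcbvmax_mode: str = "p90"
    pp_threshold: float = 0.5
    baseline_window: tuple[int, int] = (0, 8)
    nawm_radius: float = 3.0  # auto-NAWM sphere for the threshold stats
    coefficients: ModelCoefficients = field(default_factory=ModelCoefficients)
    seed: int = 0

    def digest(self) -> str:
        payload = asdict(self)
        payload["coefficients"] = list(self.coefficients.as_array())
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class CaseResult:
    features: LesionFeatures
    pp: float
    label: str
    maps: dict
    lesion_mask: np.ndarray
    reference_mask: np.ndarray
    provenance: dict


def _auto_nawm(
    seed: tuple[int, int, int],
    brain: np.ndarray,
    radius: float,
    lesion: np.ndarray | None = None,
) -> np.ndarray:
    """Sphere around the mirrored seed, clipped to brain (and non-lesion)."""
    mirrored = (brain.shape[0] - 1 - seed[0], seed[1], seed[2])
    roi = sphere_roi(brain.shape, mirrored, radius) & brain
    if lesion is not None:
        roi &= ~lesion
    return roi


def run_case(
    dwi: dtimod.DWIStack,
    dsc: dscmod.DSCSeries,
    pre_t1: dtimod.ScalarMap,
    post_t1: dtimod.ScalarMap,
    seed_voxel: tuple[int, int, int],
    brain_mask: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> CaseResult:
    """Run one case end to end and return features, PP and label.

    All volumes are assumed co-registered on a common grid (reslice
    beforehand with `roi.reslice_to_reference` when they are not). CBV is
    only computed where it is consumed: over the lesion and the
    contralateral reference region.
    """
    config = config or PipelineConfig()
    if brain_mask is None:
        thresh = 0.1 * float(np.max(pre_t1.values))
        brain_mask = pre_t1.values > thresh
        brain_mask = ndimage.binary_fill_holes(brain_mask)

    logger.info("stage dti: tensor fit + scalar maps")
    tensors = dtimod.fit_tensor(dwi, brain_mask)
    eig = dtimod.eigendecompose(tensors)
    if eig.n_clamped:
        logger.info("dti: clamped negative eigenvalues at %d voxels", eig.n_clamped)
    scalar_maps = dtimod.compute_scalar_maps(eig)

    logger.info("stage segment: enhancing lesion + contralateral reference")
    nawm_for_threshold = _auto_nawm(seed_voxel, brain_mask, config.nawm_radius)
    lesion = segment_enhancing(
        post_t1, pre_t1, seed_voxel, nawm_for_threshold, k=config.k_sigma
    )
    reference = mirror_contralateral(
        lesion.mask, lesion=lesion.mask, brain_mask=brain_mask
    )

    logger.info("stage dsc: dR2* + gamma-variate CBV over lesion and reference")
    conc = dscmod.signal_to_deltaR2star(
        dsc, baseline=config.baseline_window, mask=brain_mask
    )
    work = lesion.mask | reference.mask
    cbv = dscmod.cbv_map(conc, mask=work)
    rcbv = dscmod.normalize_rcbv(cbv, reference.mask & conc.mask)

    logger.info("stage features + prediction")
    maps = {name: m.values for name, m in scalar_maps.items()}
    maps["rCBV"] = rcbv
    feats = extract_features(maps, lesion.mask, rcbvmax_mode=config.rcbvmax_mode)
    pp = predictive_probability(
        feats.fa_median, feats.cl_median, feats.rcbv_max, config.coefficients
    )
    label = classify(pp, config.pp_threshold)
    return CaseResult(
        features=feats,
        pp=float(pp),
        label=str(label),
        maps={**scalar_maps, "rCBV": dtimod.ScalarMap("rCBV", rcbv, dwi.affine)},
        lesion_mask=lesion.mask,
        reference_mask=reference.mask,
        provenance={"config_hash": config.digest(), "seed": config.seed},
    )


def validate_cohort(
    table: pd.DataFrame,
    config: PipelineConfig | None = None,
    run_loocv: bool = True,
) -> dict:
    """Cohort validation report from a feature table with ground truth.

    ``table`` needs columns fa_median, cl_median, rcbv_max, truth_label
    (and optionally pp/predicted_label, which are computed when absent).
    """
    config = config or PipelineConfig()
    df = table.copy()
    if "pp" not in df:
        df["pp"] = predictive_probability(
            df["fa_median"], df["cl_median"], df["rcbv_max"], config.coefficients
        )
    if "predicted_label" not in df:
        df["predicted_label"] = classify(df["pp"].to_numpy(), config.pp_threshold)

    truth = df["truth_label"].to_numpy()
    confusion = summarize_cohort(df["predicted_label"].to_numpy(), truth)
    X = df[list(FEATURES)].to_numpy()

    report: dict = {
        "n": len(df),
        "confusion": {
            "n_psp": confusion.n_psp,
            "n_psp_correct": confusion.n_psp_correct,
            "n_tp": confusion.n_tp,
            "n_tp_correct": confusion.n_tp_correct,
            "concordance_pct": confusion.concordance_pct,
            **{f"{k}_rounded": v for k, v in confusion.rounded().items()},
        },
        "group_stats": {},
        "mann_whitney": {},
        "config_hash": config.digest(),
    }
    tp_rows = df[df["truth_label"] == TP_MIXED]
    psp_rows = df[df["truth_label"] == PSP]
    for feat in FEATURES:
        report["group_stats"][feat] = {
            "tp_mixed_mean": float(tp_rows[feat].mean()) if len(tp_rows) else None,
            "tp_mixed_sd": float(tp_rows[feat].std(ddof=1)) if len(tp_rows) > 1 else None,
            "psp_mean": float(psp_rows[feat].mean()) if len(psp_rows) else None,
            "psp_sd": float(psp_rows[feat].std(ddof=1)) if len(psp_rows) > 1 else None,
            "ks_gate": (
                ks_normality_gate(df[feat].to_numpy())["distribution"]
                if len(df) >= 5
                else None
            ),
        }
        if len(tp_rows) and len(psp_rows):
            u, p = mann_whitney(tp_rows[feat].to_numpy(), psp_rows[feat].to_numpy())
            report["mann_whitney"][feat] = {"U": u, "p": p}

    if len(df) >= 3 and np.ptp(df["pp"].to_numpy()) > 0 and len(tp_rows) and len(psp_rows):
        r, p_r = concordance_pearson(df["pp"].to_numpy(), truth)
        report["concordance_r"] = {"r": r, "p": p_r}
    else:
        report["concordance_r"] = None
    report["pp_group_means_pct"] = {
        "tp_mixed": 100.0 * float(tp_rows["pp"].mean()) if len(tp_rows) else None,
        "psp": 100.0 * float(psp_rows["pp"].mean()) if len(psp_rows) else None,
    }
    if len(tp_rows) and len(psp_rows):
        roc = roc_auc(df["pp"].to_numpy(), truth)
        report["roc"] = {"auc": roc.auc}
    else:
        report["roc"] = None
    if run_loocv and len(df) >= 10:
        cv = loocv(X, truth, refit=True)
        report["loocv"] = {
            "accuracy": cv.accuracy,
            "accuracy_pct": 100.0 * cv.accuracy,
            "n_flagged": cv.n_flagged,
        }
    return report


def run_cohort(
    cases: list[dict] | pd.DataFrame,
    config: PipelineConfig | None = None,
    run_loocv: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Cohort driver: per-case pipeline (or direct feature ingestion),
    then validation statistics.

    ``cases`` is either a feature table (columns fa_median, cl_median,
    rcbv_max, truth_label) or a list of dicts with the `run_case` volume
    inputs plus 'truth_label'. Per-case failures are logged and excluded;
    the report carries the exclusion count.
    """
    config = config or PipelineConfig()
    if isinstance(cases, pd.DataFrame):
        table = cases.copy()
        n_failed = 0
    else:
        rows, n_failed = [], 0
        for i, case in enumerate(cases):
            cid = case.get("case_id", f"case{i:03d}")
            try:
                res = run_case(
                    case["dwi"],
                    case["dsc"],
                    case["pre_t1"],
                    case["post_t1"],
                    case["seed_voxel"],
                    case.get("brain_mask"),
                    config,
                )
            except Exception as exc:  # noqa: BLE001 - per-case isolation
                logger.warning("case %s failed: %s", cid, exc)
                n_failed += 1
                continue
            rows.append(
                {
                    "case_id": cid,
                    **res.features.as_dict(),
                    "pp": res.pp,
                    "predicted_label": res.label,
                    "truth_label": case["truth_label"],
                }
            )
        if len(rows) < 2:
            raise ValueError("fewer than 2 usable cases in the cohort")
        table = pd.DataFrame(rows)
    report = validate_cohort(table, config, run_loocv=run_loocv)
    report["n_excluded"] = n_failed
    return table, report
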