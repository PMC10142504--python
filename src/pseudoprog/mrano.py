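"""Radiographic response assessment from serial SPD measurements.

When no tissue is available, the reference label comes from modified RANO
criteria applied to the sum of products of perpendicular diameters (SPD)
of enhancing lesions on serial post-contrast T1 scans: progression is a
>= 25% SPD increase over the nadir, confirmed on a scan at least 28 days
later; pseudoprogression is an initial increase that subsequently settles
(< 25% above nadir) across consecutive follow-ups; anything the timeline
cannot adjudicate is indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import PSP, TP_MIXED

__all__ = [
    "MRANOConfig",
    "LesionMeasurement",
    "RadiographicAssessment",
    "compute_spd",
    "assess_response",
    "INDETERMINATE",
]

INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class MRANOConfig:
    """Numeric thresholds of the SPD rule (configurable, not hard-coded)."""

    progression_fraction: float = 0.25  # >=25% SPD increase over nadir
    confirmation_days: int = 28  # >=4-week persistence


@dataclass
class LesionMeasurement:
    """One scan: day since chemoradiation completion and diameter pairs (cm)."""

    day: float
    diameter_pairs: list[tuple[float, float]] = field(default_factory=list)

    @property
    def spd(self) -> float:
        return compute_spd(self.diameter_pairs)


@dataclass
class RadiographicAssessment:
    category: str  # PsP | TP+mixed | indeterminate
    supporting_scans: list[int]
    confirmed: bool


def compute_spd(pairs: list[tuple[float, float]]) -> float:
    """Sum of products of perpendicular diameters, cm^2.

    An empty list is measurable-disease-free and returns 0; non-positive
    diameters are input errors.
    """
    total = 0.0
    for d1, d2 in pairs:
        if d1 <= 0 or d2 <= 0:
            raise ValueError("diameters must be positive")
        total += d1 * d2
    return total


def assess_response(
    timeline: list[LesionMeasurement], config: MRANOConfig = MRANOConfig()
) -> RadiographicAssessment:
    """Classify a chronologic SPD timeline as TP+mixed, PsP or indeterminate.

    TP+mixed: a >= 25% SPD increase over the nadir, still >= 25% above
    that nadir on a scan >= 28 days later. PsP: no confirmed progression
    and the two most recent consecutive scans sit < 25% above nadir, with
    the timeline long enough to satisfy the 4-week persistence rule.
    Otherwise indeterminate.
    """
    if len(timeline) < 2:
        raise ValueError("need at least 2 scans")
    days = [m.day for m in timeline]
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError("scans must be in chronologic order")
    spd = [m.spd for m in timeline]
    grow = 1.0 + config.progression_fraction

    # candidate progression events: scan i with SPD >= (1+f) * nadir(before i)
    for i in range(1, len(spd)):
        nadir = min(spd[:i])
        if spd[i] >= grow * nadir:
            for j in range(i + 1, len(spd)):
                if days[j] - days[i] >= config.confirmation_days and spd[j] >= grow * nadir:
                    return RadiographicAssessment(
                        category=TP_MIXED, supporting_scans=[i, j], confirmed=True
                    )

    # stability: last two consecutive scans below the progression threshold
    last, prev = len(spd) - 1, len(spd) - 2
    def stable(idx: int) -> bool:
        if idx == 0:
            return True  # baseline defines its own nadir
        return spd[idx] < grow * min(spd[:idx])

    if stable(prev) and stable(last) and days[last] - days[0] >= config.confirmation_days:
        return RadiographicAssessment(
            category=PSP, supporting_scans=[prev, last], confirmed=True
        )
    return RadiographicAssessment(category=INDETERMINATE, supporting_scans=[], confirmed=False)
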