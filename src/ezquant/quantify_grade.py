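"""Defect-area measurement rules, gradability, and the qualitative grade.

Area rules follow reading-center measurability conventions: the raw area is
the defect pixel count times the calibrated en face pixel area; values
below the measurability floor of 0.004 mm^2 (the smallest area a grader can
call) are reported as zero, and the report is capped at 0.78 mm^2, the area
of the central subfield itself.  The presence variable is strict:
``present`` iff the reported area exceeds 0.004 mm^2, so a raw area of
exactly 0.004 mm^2 is reported as measurable but counted as no-defect — a
measure-zero boundary that cannot affect cohort statistics.

The qualitative grade emulates the three-step clinical scale (normal /
patchy / absent, or cannot-grade when signal blockage by hemorrhage or
fluid hides the outer retina).  Human graders carry no numeric thresholds;
here the grade is the defect fraction of the CSF disc area against two
configurable cutoffs, with an optional grader-noise mode that flips
adjacent categories to emulate intergrader variability.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .enface import CSFMask, CSF_DISC_AREA_MM2
from .geometry import ScanGeometry

__all__ = [
    "MIN_DEFECT_AREA_MM2",
    "MAX_DEFECT_AREA_MM2",
    "DefectMeasure",
    "EZGrade",
    "GradabilityReport",
    "GradeThresholds",
    "GradabilityConfig",
    "measure_defect",
    "assess_gradability",
    "qualitative_grade",
]

#: measurability floor (drusen circle C0 convention)
MIN_DEFECT_AREA_MM2 = 0.004
#: cap: the area of the central subfield
MAX_DEFECT_AREA_MM2 = 0.78


class EZGrade(str, enum.Enum):
    normal = "normal"
    patchy = "patchy"
    absent = "absent"
    cannot_grade = "cannot_grade"


@dataclass(frozen=True)
class DefectMeasure:
    raw_area_mm2: float
    reported_area_mm2: float
    present: bool


@dataclass(frozen=True)
class GradabilityReport:
    gradable: bool
    blocked_fraction: float


@dataclass(frozen=True)
class GradeThresholds:
    """Defect fraction of the CSF disc separating the grade categories."""

    t_normal: float = 0.02  # below: normal
    t_absent: float = 0.50  # at or above: absent

    def __post_init__(self) -> None:
        if self.t_normal >= self.t_absent:
            raise ValueError("t_normal must be < t_absent")


@dataclass(frozen=True)
class GradabilityConfig:
    quality_cutoff: float = 0.3  # signal index below which a column is blocked
    blocked_cutoff: float = 0.25  # blocked CSF fraction above which ungradable


def measure_defect(mask, geometry: ScanGeometry) -> DefectMeasure:
    """Apply the floor/cap rules to a defect mask.

    ``mask`` is a boolean en face grid (or a
    :class:`~ezquant.defect_detect.DefectMask`) already restricted to the
    CSF.  Total area (the union of defect pixels) is measured; shape and
    location are deliberately not characterized.
    """
    grid = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if grid.shape != geometry.en_face_shape:
        raise ValueError(
            f"mask shape {grid.shape} does not match geometry "
            f"{geometry.en_face_shape}"
        )
    raw = float(np.count_nonzero(grid) * geometry.en_face_pixel_area_mm2)
    if raw < MIN_DEFECT_AREA_MM2:
        reported = 0.0
    else:
        reported = min(raw, MAX_DEFECT_AREA_MM2)
    return DefectMeasure(
        raw_area_mm2=raw,
        reported_area_mm2=reported,
        present=reported > MIN_DEFECT_AREA_MM2,
    )


def assess_gradability(
    quality,
    csf: CSFMask,
    config: GradabilityConfig | None = None,
) -> GradabilityReport:
    """Decide gradability from the per-column signal-quality grid.

    ``quality`` is either the (n_bscans, n_ascans) grid or a list of
    per-B-scan quality vectors.  ``blocked_fraction`` is the fraction of CSF
    columns whose signal index falls below the quality cutoff; the scan is
    gradable iff that fraction does not exceed the blocked cutoff.
    """
    config = config or GradabilityConfig()
    grid = np.stack(quality) if isinstance(quality, (list, tuple)) else np.asarray(quality)
    if grid.shape != csf.mask.shape:
        raise ValueError("quality grid shape does not match the CSF mask")
    n_csf = int(csf.mask.sum())
    if n_csf == 0:
        return GradabilityReport(gradable=False, blocked_fraction=1.0)
    blocked = float(np.count_nonzero((grid < config.quality_cutoff) & csf.mask) / n_csf)
    return GradabilityReport(
        gradable=blocked <= config.blocked_cutoff, blocked_fraction=blocked
    )


_GRADE_ORDER = [EZGrade.normal, EZGrade.patchy, EZGrade.absent]


def qualitative_grade(
    measure: DefectMeasure,
    gradability: GradabilityReport,
    thresholds: GradeThresholds | None = None,
    grader_flip_prob: float = 0.0,
    grader_noise_seed: int | None = None,
) -> EZGrade:
    """Three-step qualitative grade of the EZ within the CSF.

    ``cannot_grade`` takes precedence whenever the scan is ungradable.
    Otherwise the defect fraction of the CSF disc area decides: normal
    below ``t_normal``, absent at or above ``t_absent``, patchy between.
    With ``grader_flip_prob`` > 0 the grade flips to an adjacent category
    with that probability, emulating human intergrader noise (which lets
    eyes with measurable defects still receive a grade of normal).
    """
    if not gradability.gradable:
        return EZGrade.cannot_grade
    thresholds = thresholds or GradeThresholds()
    fraction = measure.reported_area_mm2 / CSF_DISC_AREA_MM2
    if fraction < thresholds.t_normal:
        grade = EZGrade.normal
    elif fraction >= thresholds.t_absent:
        grade = EZGrade.absent
    else:
        grade = EZGrade.patchy
    if grader_flip_prob > 0.0:
        rng = np.random.default_rng(grader_noise_seed)
        if rng.random() < grader_flip_prob:
            i = _GRADE_ORDER.index(grade)
            if i == 0:
                grade = _GRADE_ORDER[1]
            elif i == 2:
                grade = _GRADE_ORDER[1]
            else:
                grade = _GRADE_ORDER[0 if rng.random() < 0.5 else 2]
    return grade
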