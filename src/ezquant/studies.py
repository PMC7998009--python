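"""Phantom validation studies: end-to-end area recovery, segmentation
Dice, and AR(1) parameter recovery.

These are the package's built-in agreement/calibration experiments: every
quantity is recomputed from freshly simulated data, never looked up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import fit_ar1_longitudinal
from .enface import csf_mask
from .geometry import make_geometry
from .layer_seg import segment_volume
from .oct_synth import CohortParams, child_seed, simulate_cohort
from .pipeline import make_eye_volume, process_volume, train_default_classifier

__all__ = [
    "icc_oneway",
    "AreaRecoveryResult",
    "area_recovery_study",
    "segmentation_dice_study",
    "Ar1RecoveryResult",
    "ar1_recovery_study",
]


def icc_oneway(x, y) -> float:
    """One-way random-effects intraclass correlation ICC(1,1) between two
    measurements of the same subjects."""
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    msb = k * ((subj_means - grand) ** 2).sum() / (n - 1)
    msw = ((data - subj_means[:, None]) ** 2).sum() / (n * (k - 1))
    return float((msb - msw) / (msb + (k - 1) * msw))


@dataclass
class AreaRecoveryResult:
    table: pd.DataFrame  # columns: true_area_mm2, reported_area_mm2
    icc: float
    mean_bias_mm2: float
    n_eyes: int


def area_recovery_study(
    n_eyes: int = 50,
    area_range: tuple[float, float] = (0.01, 0.26),
    seed: int = 0,
    noise_sd: float = 0.1,
    train_eyes: int = 8,
    dialect: str = "cirrus6mm",
) -> AreaRecoveryResult:
    """End-to-end agreement between reported and true defect areas.

    Trains the pixel classifier on its own phantom set, then runs the full
    segmentation -> mapping -> classification -> quantification chain on
    ``n_eyes`` held-out eyes whose lesion areas span ``area_range``
    (the span of grade-stratum mean areas).  Truth per eye is the
    rasterized defect area inside the CSF.
    """
    geometry = make_geometry(dialect)
    csf = csf_mask(geometry)
    model = train_default_classifier(
        geometry,
        n_train=train_eyes,
        seed=child_seed(seed, "area-study-train"),
        noise_sd=noise_sd,
    )
    rng = np.random.default_rng(child_seed(seed, "area-study-eyes"))
    lo, hi = area_range
    rows = []
    for i in range(n_eyes):
        nominal = lo + (hi - lo) * i / max(n_eyes - 1, 1)
        vol, truth = make_eye_volume(
            geometry,
            nominal,
            ungradable=False,
            seed=int(rng.integers(0, 2**31)),
            noise_sd=noise_sd,
        )
        res = process_volume(vol, model, csf)
        rows.append(
            {
                "true_area_mm2": truth.true_defect_area_mm2,
                "reported_area_mm2": res.reported_area_mm2,
            }
        )
    table = pd.DataFrame(rows)
    return AreaRecoveryResult(
        table=table,
        icc=icc_oneway(table["true_area_mm2"], table["reported_area_mm2"]),
        mean_bias_mm2=float(
            (table["reported_area_mm2"] - table["true_area_mm2"]).mean()
        ),
        n_eyes=n_eyes,
    )


def segmentation_dice_study(
    areas: tuple[float, ...] = (0.02, 0.08, 0.2),
    seed: int = 0,
    dialect: str = "cirrus6mm",
) -> tuple[float, float]:
    """(min Dice, max boundary error) of the tracker on noiseless phantoms.

    Dice compares EZ-undefined columns against the true defect footprint;
    boundary error is the mean |error| of the EZ inner border in axial
    pixels over defect-free columns, maximized over eyes.
    """
    geometry = make_geometry(dialect)
    rng = np.random.default_rng(child_seed(seed, "dice-study"))
    dices, errors = [], []
    for area in areas:
        vol, truth = make_eye_volume(
            geometry, area, False, seed=int(rng.integers(0, 2**31)), noise_sd=0.0
        )
        vb = segment_volume(vol)
        undef = ~np.isfinite(vb.ez_inner_depth)
        inter = (undef & truth.defect_mask).sum()
        dices.append(2 * inter / (undef.sum() + truth.defect_mask.sum()))
        ok = np.isfinite(vb.ez_inner_depth) & np.isfinite(truth.ez_inner_depth)
        errors.append(
            float(np.abs(vb.ez_inner_depth - truth.ez_inner_depth)[ok].mean())
        )
    return float(min(dices)), float(max(errors))


@dataclass
class Ar1RecoveryResult:
    slopes: np.ndarray  # per replicate: mean fitted area slope
    coverage: float  # fraction of per-visit 95% Wald CIs covering truth
    true_slope: float
    mc_se: float  # Monte-Carlo SE of the mean fitted slope

    @property
    def mean_slope(self) -> float:
        return float(self.slopes.mean())


def ar1_recovery_study(
    n_replicates: int = 100,
    n_participants: int = 300,
    seed: int = 0,
    **param_overrides,
) -> Ar1RecoveryResult:
    """Simulate-and-refit calibration of the AR(1) longitudinal model.

    Each replicate draws a fresh cohort at the default generating values
    (area slope -20 letters/mm^2, i.e. ~1 letter per 0.05 mm^2; rho 0.5;
    sigma 8) and refits; the per-replicate slope estimate is the mean of
    the four visit-specific area coefficients, and coverage pools the
    per-visit 95% Wald intervals.
    """
    slopes = []
    covered = 0
    total = 0
    base = child_seed(seed, "ar1-study")
    true_slope = param_overrides.get("area_slope", CohortParams().area_slope)
    for r in range(n_replicates):
        params = CohortParams(
            n_participants=n_participants,
            seed=(base + r) % (2**31),
            **param_overrides,
        )
        table = simulate_cohort(params)
        fit = fit_ar1_longitudinal(table, "area_continuous")
        names = [n for n in fit.params.index if n.startswith("area:")]
        slopes.append(float(fit.params[names].mean()))
        for name in names:
            lo, hi = fit.wald_ci(name)
            covered += int(lo <= true_slope <= hi)
            total += 1
    slopes = np.asarray(slopes)
    return Ar1RecoveryResult(
        slopes=slopes,
        coverage=covered / total,
        true_slope=float(true_slope),
        mc_se=float(slopes.std(ddof=1) / math.sqrt(len(slopes))),
    )
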