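"""Ground-truthed synthetic SD-OCT volumes and longitudinal cohorts.

The phantom emulates the features of macular volume scans that the analysis
pipeline depends on, and nothing more:

* three outer-retinal hyperreflective bands — an ELM-like band, the
  ellipsoid zone (EZ) and the retinal pigment epithelium (RPE) — rendered as
  Gaussian-profile ridges in depth whose position varies smoothly
  (low-order polynomial) across the field, plus an inner retinal surface;
* EZ defect lesions: elliptical en face footprints inside which the EZ band
  is attenuated toward background;
* shadow lesions: footprints inside which *all* bands are attenuated,
  emulating signal blockage by hemorrhage or fluid that renders a scan
  ungradable;
* a longitudinal cohort whose visual-acuity-letter-score (VALS) change
  trajectories depend linearly on contemporaneous defect area with AR(1)
  within-participant noise.

Every volume carries exact ground truth by construction, so downstream
segmentation, mapping, classification and statistics are testable without
any real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ScanGeometry

__all__ = [
    "LesionSpec",
    "OCTVolume",
    "GroundTruth",
    "CohortParams",
    "BandModel",
    "simulate_volume",
    "simulate_cohort",
    "FOLLOW_UP_VISITS",
    "ALL_VISITS",
]

FOLLOW_UP_VISITS = ("M01", "M06", "M12", "M24")
ALL_VISITS = ("BL",) + FOLLOW_UP_VISITS

# severity at or above which an ez_defect footprint counts as true EZ loss
DEFECT_SEVERITY_CUTOFF = 0.5
# attenuation factor below which a column counts as truly signal-blocked
BLOCKED_ATTENUATION_CUTOFF = 0.5
# CSF-blocked fraction above which a scan is truly ungradable
UNGRADABLE_BLOCKED_FRACTION = 0.25


class LesionError(ValueError):
    """Lesion specification outside the scanned field or malformed."""


@dataclass(frozen=True)
class LesionSpec:
    """En face lesion: EZ defect or shadowing by hemorrhage/fluid.

    ``center_mm`` is (x, y) from the field corner, x along A-scans and y
    across B-scans.  ``radius_mm`` is a scalar or an (rx, ry) pair for an
    ellipse.  ``severity`` in [0, 1] is the fractional attenuation of the
    affected bands inside the footprint.
    """

    kind: str  # "ez_defect" | "shadow"
    center_mm: tuple[float, float]
    radius_mm: float | tuple[float, float]
    severity: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("ez_defect", "shadow"):
            raise LesionError(f"unknown lesion kind {self.kind!r}")
        rx, ry = self.radii
        if rx <= 0 or ry <= 0:
            raise LesionError("lesion radius must be positive")
        if not 0.0 <= self.severity <= 1.0:
            raise LesionError("lesion severity must be in [0, 1]")

    @property
    def radii(self) -> tuple[float, float]:
        if isinstance(self.radius_mm, (tuple, list)):
            rx, ry = self.radius_mm
            return float(rx), float(ry)
        return float(self.radius_mm), float(self.radius_mm)

    def footprint(self, geometry: ScanGeometry) -> np.ndarray:
        """Boolean en face footprint by the pixel-center membership test."""
        cx, cy = self.center_mm
        rx, ry = self.radii
        x = (np.arange(geometry.n_ascans) + 0.5) * geometry.ascan_pitch_mm
        y = (np.arange(geometry.n_bscans) + 0.5) * geometry.bscan_pitch_mm
        dx = (x[None, :] - cx) / rx
        dy = (y[:, None] - cy) / ry
        return dx**2 + dy**2 <= 1.0


@dataclass(frozen=True)
class BandModel:
    """Phantom parameters for the outer-retinal band stack.

    Depths are the *inner borders* (shallowest half-prominence crossing) of
    each band in axial pixels.  Band profiles are Gaussians of width
    ``band_sigma_px``; the ridge center therefore sits
    ``band_sigma_px * sqrt(2 ln 2)`` below the stated inner border.
    """

    ez_inner_px: float = 270.0
    ez_rpe_gap_px: float = 30.0
    elm_offset_px: float = 12.0  # ELM sits this far above the EZ
    ilm_px: float = 100.0  # inner retinal surface
    band_sigma_px: float = 2.0
    amp_rpe: float = 1.0
    amp_ez: float = 0.8
    amp_elm: float = 0.45
    amp_ilm: float = 0.55
    background: float = 0.05
    tilt_px: float = 6.0  # max linear depth variation across the field
    bowl_px: float = 5.0  # max quadratic (foveal bowl) depth variation


@dataclass
class OCTVolume:
    """Intensity volume, shape (n_bscans, n_axial, n_ascans)."""

    data: np.ndarray
    geometry: ScanGeometry

    def bscan(self, b: int) -> np.ndarray:
        """One B-scan as an (n_axial, n_ascans) image."""
        return self.data[b]


@dataclass
class GroundTruth:
    """Exact truth for one synthetic volume.

    ``ez_inner_depth`` is NaN inside the true defect footprint;
    ``attenuation`` is the per-pixel multiplicative shadow factor in (0, 1].
    """

    ez_inner_depth: np.ndarray
    rpe_inner_depth: np.ndarray
    defect_mask: np.ndarray
    true_defect_area_mm2: float
    gradable: bool
    attenuation: np.ndarray
    blocked_fraction: float


def _smooth_depth_field(
    base: float, geometry: ScanGeometry, rng: np.random.Generator, band: BandModel
) -> np.ndarray:
    """Low-order polynomial depth variation across the en face field."""
    u = np.linspace(-1.0, 1.0, geometry.n_ascans)[None, :]
    v = np.linspace(-1.0, 1.0, geometry.n_bscans)[:, None]
    tx, ty = rng.uniform(-band.tilt_px, band.tilt_px, size=2)
    bowl = rng.uniform(0.0, band.bowl_px)
    return base + tx * u + ty * v + bowl * (u**2 + v**2)


def _add_band(
    volume: np.ndarray,
    inner_depth: np.ndarray,
    amplitude: np.ndarray | float,
    sigma: float,
) -> None:
    """Accumulate a Gaussian ridge whose rising half-max edge is at
    ``inner_depth``.  Only the depth slab within 5 sigma of the ridge is
    touched, which keeps synthesis fast."""
    center = inner_depth + sigma * math.sqrt(2.0 * math.log(2.0))
    zlo = max(0, int(np.floor(center.min() - 5 * sigma)))
    zhi = min(volume.shape[1], int(np.ceil(center.max() + 5 * sigma)) + 1)
    if zhi <= zlo:
        return
    z = np.arange(zlo, zhi, dtype=np.float32)
    # (n_bscans, slab, n_ascans)
    dz = z[None, :, None] - center[:, None, :].astype(np.float32)
    profile = np.exp(-0.5 * (dz / sigma) ** 2)
    if np.isscalar(amplitude):
        profile *= amplitude
    else:
        profile *= np.asarray(amplitude, dtype=np.float32)[:, None, :]
    volume[:, zlo:zhi, :] += profile


def simulate_volume(
    geometry: ScanGeometry,
    lesions: list[LesionSpec] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    band: BandModel = BandModel(),
) -> tuple[OCTVolume, GroundTruth]:
    """Synthesize one macular volume with exact ground truth.

    Parameters
    ----------
    geometry
        Scan geometry (dimensions and calibration).
    lesions
        EZ defects and/or shadows; all must lie within the scanned field.
    noise_sd
        SD of additive Gaussian intensity noise (band amplitudes are O(1)).
    seed
        Seeds both the smooth depth fields and the noise; identical seeds
        give bit-identical volumes.

    Returns
    -------
    (OCTVolume, GroundTruth)
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lesions = list(lesions or [])
    for les in lesions:
        cx, cy = les.center_mm
        if not (0.0 <= cx <= geometry.lateral_extent_mm) or not (
            0.0 <= cy <= geometry.bscan_extent_mm
        ):
            raise LesionError(
                f"lesion center {les.center_mm} outside the "
                f"{geometry.lateral_extent_mm:.2f} x "
                f"{geometry.bscan_extent_mm:.2f} mm field"
            )

    rng = np.random.default_rng(seed)
    ez_depth = _smooth_depth_field(band.ez_inner_px, geometry, rng, band)
    rpe_depth = ez_depth + band.ez_rpe_gap_px
    if rpe_depth.max() + 6 * band.band_sigma_px >= geometry.n_axial:
        raise ValueError("band model places RPE below the scan depth range")

    shape = geometry.en_face_shape
    ez_amp = np.full(shape, band.amp_ez, dtype=np.float32)
    attenuation = np.ones(shape, dtype=np.float32)
    defect_mask = np.zeros(shape, dtype=bool)
    for les in lesions:
        fp = les.footprint(geometry)
        if les.kind == "ez_defect":
            ez_amp[fp] *= 1.0 - les.severity
            if les.severity >= DEFECT_SEVERITY_CUTOFF:
                defect_mask |= fp
        else:  # shadow
            attenuation[fp] *= 1.0 - les.severity

    volume = np.full(
        (geometry.n_bscans, geometry.n_axial, geometry.n_ascans),
        band.background,
        dtype=np.float32,
    )
    flat = np.full(shape, band.ilm_px)
    _add_band(volume, flat, band.amp_ilm, band.band_sigma_px)
    _add_band(volume, ez_depth - band.elm_offset_px, band.amp_elm, band.band_sigma_px)
    _add_band(volume, ez_depth, ez_amp, band.band_sigma_px)
    _add_band(volume, rpe_depth, band.amp_rpe, band.band_sigma_px)
    volume *= attenuation[:, None, :]
    if noise_sd > 0:
        noise = rng.standard_normal(size=volume.shape, dtype=np.float32)
        volume += np.float32(noise_sd) * noise

    # ground-truth bookkeeping inside the central subfield
    from .enface import csf_mask  # local import: enface depends only on geometry

    csf = csf_mask(geometry)
    pixel_area = geometry.en_face_pixel_area_mm2
    true_area = float(np.count_nonzero(defect_mask & csf.mask) * pixel_area)
    blocked = attenuation < BLOCKED_ATTENUATION_CUTOFF
    blocked_fraction = float(np.count_nonzero(blocked & csf.mask) / csf.mask.sum())
    gradable = blocked_fraction <= UNGRADABLE_BLOCKED_FRACTION

    ez_true = ez_depth.copy()
    ez_true[defect_mask] = np.nan
    truth = GroundTruth(
        ez_inner_depth=ez_true,
        rpe_inner_depth=rpe_depth,
        defect_mask=defect_mask,
        true_defect_area_mm2=true_area,
        gradable=gradable,
        attenuation=attenuation,
        blocked_fraction=blocked_fraction,
    )
    return OCTVolume(data=volume, geometry=geometry), truth


# ---------------------------------------------------------------------------
# Longitudinal cohort
# ---------------------------------------------------------------------------

#: ungradable-scan rates observed in the source cohort (BL dominated by
#: hemorrhage/fluid blockage, improving under treatment)
DEFAULT_UNGRADABLE_RATE = {
    "BL": 0.77,
    "M01": 0.343,
    "M06": 0.102,
    "M12": 0.086,
    "M24": 0.093,
}
#: per-visit missed-visit (attrition) rates
DEFAULT_MISSING_RATE = {"BL": 0.0, "M01": 0.025, "M06": 0.022, "M12": 0.097, "M24": 0.376}
#: VALS-change intercepts (letters) at zero defect area, per follow-up visit
DEFAULT_VISIT_EFFECTS = {"M01": 15.4, "M06": 20.8, "M12": 22.5, "M24": 19.8}
#: per-visit mean central-subfield thickness (um) for the clinical covariate
_CSF_THICKNESS_MEAN = {"M01": 299.7, "M06": 260.5, "M12": 253.9, "M24": 310.7}


@dataclass(frozen=True)
class CohortParams:
    """Generating parameters of the longitudinal synthetic cohort.

    VALS change from baseline at follow-up visit v is
    ``visit_effects[v] + area_slope * area_v + eps_v`` with ``eps`` a
    zero-mean AR(1) process (correlation ``rho``, marginal SD ``sigma``
    letters) across the ordered visits M01, M06, M12, M24.

    Defect areas are zero-inflated log-normal: a participant is
    defect-prone with probability ``1 - p_zero_area``; prone participants
    carry a log-normal base area jittered per visit.  Defaults give a
    cohort-mean area near 0.07 mm^2 with SD near 0.16 mm^2 at M01.

    Baseline VALS is uniform on the eligibility window [19, 73] minus
    ``baseline_area_slope`` times the participant's latent defect burden
    (clipped back to the window): defect-prone eyes enter the study with
    worse acuity, which is what separates the VALS *levels* of defect and
    no-defect eyes beyond the contemporaneous area effect.
    """

    n_participants: int = 362
    visit_effects: dict = field(default_factory=lambda: dict(DEFAULT_VISIT_EFFECTS))
    area_slope: float = -20.0  # letters per mm^2 (0.05 mm^2 => -1 letter)
    # baseline acuity penalty per mm^2 of a participant's latent defect
    # burden: photoreceptor damage costs letters before treatment too, which
    # is what separates the defect/no-defect VALS trajectories by ~10
    # letters rather than the ~1-letter contemporaneous effect alone
    baseline_area_slope: float = -75.0
    rho: float = 0.5
    sigma: float = 8.0
    missing_rate: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATE))
    ungradable_rate: dict = field(
        default_factory=lambda: dict(DEFAULT_UNGRADABLE_RATE)
    )
    p_zero_area: float = 0.487
    area_log_mu: float = -2.572
    area_log_sigma: float = 1.078
    area_visit_jitter: float = 0.35  # SD of per-visit log-area jitter
    area_cap_mm2: float = 0.78
    grade_t_normal: float = 0.02  # defect fraction of CSF below which "normal"
    grade_t_absent: float = 0.50  # defect fraction of CSF at/above which "absent"
    seed: int = 0

    def validate(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for name, rates in (
            ("missing_rate", self.missing_rate),
            ("ungradable_rate", self.ungradable_rate),
        ):
            for v, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"{name}[{v}] = {r} outside [0, 1]")
        if not 0.0 <= self.p_zero_area <= 1.0:
            raise ValueError("p_zero_area outside [0, 1]")
        if self.grade_t_normal >= self.grade_t_absent:
            raise ValueError("grade_t_normal must be < grade_t_absent")


def _ar1_noise(
    rng: np.random.Generator, n: int, k: int, rho: float, sigma: float
) -> np.ndarray:
    """n x k draws of a stationary AR(1) process with marginal SD sigma."""
    eps = np.empty((n, k))
    eps[:, 0] = rng.normal(0.0, sigma, size=n)
    innov_sd = sigma * math.sqrt(1.0 - rho**2)
    for t in range(1, k):
        eps[:, t] = rho * eps[:, t - 1] + rng.normal(0.0, innov_sd, size=n)
    return eps


def _grade_from_area(area: float, params: CohortParams) -> str:
    frac = area / (math.pi * 0.25)
    if frac < params.grade_t_normal:
        return "normal"
    if frac >= params.grade_t_absent:
        return "absent"
    return "patchy"


def simulate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Generate a longitudinal participant x visit table.

    Returns a DataFrame with one row per participant and visit
    (BL, M01, M06, M12, M24) and columns ``participant_id``, ``visit``,
    ``vals_letters``, ``csf_thickness_um``, ``defect_area_mm2``, ``grade``,
    ``gradable``, ``true_area_mm2``, ``vals_change``.  Missing visits keep
    their row with NaN outcomes; ungradable visits have NaN measured area
    and grade ``cannot_grade`` but retain the latent ``true_area_mm2``.
    """
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    k = len(FOLLOW_UP_VISITS)

    baseline_vals = rng.integers(19, 74, size=n)
    prone = rng.random(n) < (1.0 - params.p_zero_area)
    base_area = np.exp(
        rng.normal(params.area_log_mu, params.area_log_sigma, size=n)
    )
    # defect burden depresses baseline acuity, within the eligibility window
    burden = np.where(prone, np.minimum(base_area, params.area_cap_mm2), 0.0)
    baseline_vals = np.clip(
        np.round(baseline_vals + params.baseline_area_slope * burden), 19, 73
    ).astype(int)
    jitter = np.exp(rng.normal(0.0, params.area_visit_jitter, size=(n, k + 1)))
    areas = np.where(prone[:, None], base_area[:, None] * jitter, 0.0)
    areas = np.minimum(areas, params.area_cap_mm2)  # CSF cap

    eps = _ar1_noise(rng, n, k, params.rho, params.sigma)
    missing = {
        v: rng.random(n) < params.missing_rate.get(v, 0.0) for v in ALL_VISITS
    }
    ungradable = {
        v: rng.random(n) < params.ungradable_rate.get(v, 0.0) for v in ALL_VISITS
    }

    rows = []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        for j, visit in enumerate(ALL_VISITS):
            true_area = float(areas[i, j])
            if visit == "BL":
                change = 0.0
                csf_th = 300.0 + rng.exponential(180.0)
            else:
                t = j - 1
                change = (
                    params.visit_effects[visit]
                    + params.area_slope * true_area
                    + eps[i, t]
                )
                csf_th = max(
                    100.0, rng.normal(_CSF_THICKNESS_MEAN[visit], 110.0)
                )
            vals = int(np.clip(round(baseline_vals[i] + change), 0, 100))
            # observed change: difference of recorded letter scores
            obs_change = float(vals - baseline_vals[i])
            is_missing = bool(missing[visit][i])
            is_ungradable = bool(ungradable[visit][i])
            if is_missing:
                vals_out = np.nan
                csf_out = np.nan
                area_out = np.nan
                grade = None
                gradable = None
            elif is_ungradable:
                vals_out = vals
                csf_out = csf_th
                area_out = np.nan
                grade = "cannot_grade"
                gradable = False
            else:
                vals_out = vals
                csf_out = csf_th
                area_out = true_area
                grade = _grade_from_area(true_area, params)
                gradable = True
            rows.append(
                {
                    "participant_id": pid,
                    "visit": visit,
                    "vals_letters": vals_out,
                    "csf_thickness_um": csf_out,
                    "defect_area_mm2": area_out,
                    "grade": grade,
                    "gradable": gradable,
                    "true_area_mm2": true_area,
                    "vals_change": np.nan if is_missing else obs_change,
                }
            )
    table = pd.DataFrame(rows)
    table["visit"] = pd.Categorical(table["visit"], categories=list(ALL_VISITS), ordered=True)
    return table


def child_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage child seed (< 2**31) from a global seed."""
    import hashlib

    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
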