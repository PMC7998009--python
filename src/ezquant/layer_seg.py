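"""EZ / RPE boundary segmentation and per-A-scan signal quality.

The segmentation target is the pair of inner (shallower) borders of the
second and third outer hyperreflective bands: the ellipsoid zone (EZ) and
the retinal pigment epithelium (RPE).  The algorithm is automatic and
deterministic:

1. smooth each A-scan profile along depth;
2. detect the vitreoretinal surface (first strong rising edge per column);
3. take the brightest ridge below the surface as the RPE;
4. take the deepest qualifying local maximum in a gap window above the RPE
   as the EZ; columns whose best candidate has prominence below a fraction
   of the RPE prominence get an *undefined* EZ — these are defect
   candidates;
5. refine each ridge to its inner border, the shallowest depth at which the
   band profile exceeds half its prominence;
6. median-smooth boundaries across columns.

All decision rules are ratios of intensity differences, so the output is
invariant to global affine rescaling of the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter1d

from .geometry import ScanGeometry
from .oct_synth import OCTVolume

__all__ = [
    "SegmentationConfig",
    "BoundaryPair",
    "VolumeBoundaries",
    "segment_bscan",
    "segment_volume",
    "signal_quality",
    "volume_signal_quality",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the boundary tracker (all in pixels or ratios)."""

    depth_smooth_sigma: float = 1.0  # Gaussian smoothing along depth
    surface_margin_px: int = 40  # RPE search starts this far below the surface
    surface_rel_threshold: float = 0.3  # rising-edge fraction for the surface
    background_quantile: float = 0.2  # per-column background estimate
    rpe_rel_threshold: float = 0.2  # RPE prominence vs scan median to count as found
    ez_gap_min_px: int = 8  # EZ must sit at least this far above the RPE
    ez_gap_max_px: int = 55  # ... and at most this far
    ez_prominence_ratio: float = 0.55  # EZ/RPE prominence to accept an EZ ridge
    median_width: int = 5  # cross-column median smoothing window
    failure_fraction: float = 0.5  # undetected-RPE fraction signalling failure


@dataclass
class BoundaryPair:
    """Per-A-scan boundaries of one B-scan.

    ``ez_inner_depth`` is NaN where no qualifying EZ ridge exists (candidate
    defect); ``rpe_inner_depth`` is NaN where the RPE itself is undetectable
    (signal blockage).  ``confidence`` is the EZ/RPE prominence ratio clipped
    to [0, 1]; ``rpe_prominence`` is kept for signal-quality estimation.
    """

    ez_inner_depth: np.ndarray
    rpe_inner_depth: np.ndarray
    confidence: np.ndarray
    rpe_prominence: np.ndarray
    rpe_detected: np.ndarray

    @property
    def failed(self) -> bool:
        """Scan-level failure: RPE undetectable in too many columns."""
        return float(np.mean(~self.rpe_detected)) > 0.5


@dataclass
class VolumeBoundaries:
    """Stacked boundaries for a whole volume, shape (n_bscans, n_ascans)."""

    ez_inner_depth: np.ndarray
    rpe_inner_depth: np.ndarray
    confidence: np.ndarray
    rpe_prominence: np.ndarray
    rpe_detected: np.ndarray
    geometry: ScanGeometry

    def bscan(self, b: int) -> BoundaryPair:
        return BoundaryPair(
            ez_inner_depth=self.ez_inner_depth[b],
            rpe_inner_depth=self.rpe_inner_depth[b],
            confidence=self.confidence[b],
            rpe_prominence=self.rpe_prominence[b],
            rpe_detected=self.rpe_detected[b],
        )


def _refine_inner_border(
    sm: np.ndarray, peak: np.ndarray, prominence: np.ndarray, bg: np.ndarray, width: int
) -> np.ndarray:
    """Shallowest depth above the peak where the profile exceeds half its
    prominence (the band's inner border)."""
    n_axial = sm.shape[1]
    ks = np.arange(width + 1)[None, :, None]
    idx = np.clip(peak[:, None, :] - width + ks, 0, n_axial - 1)
    vals = np.take_along_axis(sm, idx, axis=1)
    thresh = (bg + 0.5 * prominence)[:, None, :]
    first = (vals >= thresh).argmax(axis=1)
    return (peak - width + first).astype(np.float64)


def _nanmedian_columns(depth: np.ndarray, width: int) -> np.ndarray:
    """Median filter along the A-scan axis, NaN-aware, edge-padded."""
    if width <= 1:
        return depth
    half = width // 2
    padded = np.pad(depth, ((0, 0), (half, half)), mode="edge")
    windows = sliding_window_view(padded, width, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmedian(windows, axis=-1)
    out[np.isnan(depth)] = np.nan
    return out


def _segment_stack(
    stack: np.ndarray, config: SegmentationConfig
) -> tuple[np.ndarray, ...]:
    """Core tracker on a (n_bscans, n_axial, n_ascans) stack."""
    n_b, n_axial, n_a = stack.shape
    sm = gaussian_filter1d(
        stack.astype(np.float32, copy=False), config.depth_smooth_sigma, axis=1
    )
    kbg = max(0, int(config.background_quantile * n_axial) - 1)
    bg = np.partition(sm, kbg, axis=1)[:, kbg, :]
    colmax = sm.max(axis=1)

    # vitreoretinal surface: first crossing of a relative rising threshold
    surf_thresh = bg + config.surface_rel_threshold * (colmax - bg)
    surface = (sm >= surf_thresh[:, None, :]).argmax(axis=1)

    # RPE = brightest ridge below the surface margin
    z = np.arange(n_axial, dtype=np.int64)[None, :, None]
    smr = np.where(
        z >= (surface[:, None, :] + config.surface_margin_px),
        sm,
        np.float32(-np.inf),
    )
    rpe_peak = smr.argmax(axis=1)
    del smr
    rpe_val = np.take_along_axis(sm, rpe_peak[:, None, :], axis=1)[:, 0, :]
    prom_rpe = rpe_val - bg
    ref = float(np.median(prom_rpe))
    rpe_detected = prom_rpe > config.rpe_rel_threshold * ref

    # EZ = deepest qualifying local maximum in the gap window above the RPE.
    # Only the depth slab that can contain EZ candidates is scanned.
    zlo = max(0, int(rpe_peak.min()) - config.ez_gap_max_px - 2)
    zhi = min(n_axial, int(rpe_peak.max()) + 2)
    sub = sm[:, zlo:zhi, :]
    zs = np.arange(zlo, zhi, dtype=np.int64)[None, :, None]
    local_max = np.zeros(sub.shape, dtype=bool)
    local_max[:, 1:-1, :] = (sub[:, 1:-1, :] > sub[:, :-2, :]) & (
        sub[:, 1:-1, :] >= sub[:, 2:, :]
    )
    window = (zs >= rpe_peak[:, None, :] - config.ez_gap_max_px) & (
        zs <= rpe_peak[:, None, :] - config.ez_gap_min_px
    )
    candidates = np.where(local_max & window, sub, np.float32(-np.inf))
    cand_val = candidates.max(axis=1)
    has_candidate = np.isfinite(cand_val)
    cand_prom = np.where(has_candidate, cand_val - bg, 0.0)
    confidence = np.clip(
        np.divide(
            cand_prom, prom_rpe, out=np.zeros_like(cand_prom), where=prom_rpe > 0
        ),
        0.0,
        1.0,
    )
    qualifies = (
        has_candidate
        & rpe_detected
        & (cand_prom >= config.ez_prominence_ratio * prom_rpe)
    )
    # deepest qualifying local maximum
    is_cand = local_max & window & (
        sub >= (bg + config.ez_prominence_ratio * prom_rpe)[:, None, :]
    )
    ez_peak = zhi - 1 - np.flip(is_cand, axis=1).argmax(axis=1)
    ez_peak = np.where(qualifies, ez_peak, rpe_peak)  # placeholder where absent
    ez_prom = np.take_along_axis(sm, ez_peak[:, None, :], axis=1)[:, 0, :] - bg

    # refine both ridges to their inner borders
    width = int(np.ceil(4 * config.depth_smooth_sigma)) + 4
    rpe_inner = _refine_inner_border(sm, rpe_peak, prom_rpe, bg, width)
    ez_inner = _refine_inner_border(sm, ez_peak, ez_prom, bg, width)
    rpe_inner[~rpe_detected] = np.nan
    ez_inner[~qualifies] = np.nan

    rpe_inner = _nanmedian_columns(rpe_inner, config.median_width)
    ez_inner = _nanmedian_columns(ez_inner, config.median_width)
    # a boundary pair must stay ordered: EZ at or above the RPE inner border
    swap = ez_inner > rpe_inner
    ez_inner[swap] = rpe_inner[swap]
    return ez_inner, rpe_inner, confidence, prom_rpe, rpe_detected


def segment_bscan(
    bscan: np.ndarray,
    geometry: ScanGeometry,
    config: SegmentationConfig | None = None,
) -> BoundaryPair:
    """Segment the EZ and RPE inner borders in a single B-scan.

    Parameters
    ----------
    bscan
        Intensity image of shape (n_axial, n_ascans).
    geometry
        The scan geometry the image must match.
    """
    config = config or SegmentationConfig()
    bscan = np.asarray(bscan)
    if bscan.shape != (geometry.n_axial, geometry.n_ascans):
        raise ValueError(
            f"B-scan shape {bscan.shape} does not match geometry "
            f"({geometry.n_axial}, {geometry.n_ascans})"
        )
    ez, rpe, conf, prom, det = _segment_stack(bscan[None], config)
    return BoundaryPair(
        ez_inner_depth=ez[0],
        rpe_inner_depth=rpe[0],
        confidence=conf[0],
        rpe_prominence=prom[0],
        rpe_detected=det[0],
    )


def segment_volume(
    volume: OCTVolume, config: SegmentationConfig | None = None
) -> VolumeBoundaries:
    """Segment every B-scan of a volume in one vectorized pass.

    The RPE-detection reference prominence is pooled over the whole volume,
    so shadowed B-scans are judged against the volume's healthy columns.
    """
    config = config or SegmentationConfig()
    geom = volume.geometry
    if volume.data.shape != (geom.n_bscans, geom.n_axial, geom.n_ascans):
        raise ValueError("volume shape does not match its geometry")
    ez, rpe, conf, prom, det = _segment_stack(volume.data, config)
    return VolumeBoundaries(
        ez_inner_depth=ez,
        rpe_inner_depth=rpe,
        confidence=conf,
        rpe_prominence=prom,
        rpe_detected=det,
        geometry=geom,
    )


def signal_quality(
    bscan: np.ndarray,
    boundaries: BoundaryPair,
    reference_prominence: float | None = None,
) -> np.ndarray:
    """Per-A-scan outer-retinal signal index in [0, 1].

    The index is the RPE band prominence normalized by a reference
    prominence (by default the median across the scan's columns), clipped to
    [0, 1].  It is invariant to global affine intensity rescaling and
    non-increasing under multiplicative attenuation of a column, which is
    exactly the signature of signal blockage by hemorrhage or fluid.
    """
    prom = boundaries.rpe_prominence
    if reference_prominence is None:
        reference_prominence = float(np.median(prom))
    if reference_prominence <= 0:
        return np.zeros_like(prom)
    return np.clip(prom / reference_prominence, 0.0, 1.0)


def volume_signal_quality(boundaries: VolumeBoundaries) -> np.ndarray:
    """Signal-quality grid (n_bscans, n_ascans) with a volume-wide reference."""
    prom = boundaries.rpe_prominence
    ref = float(np.median(prom))
    if ref <= 0:
        return np.zeros_like(prom)
    return np.clip(prom / ref, 0.0, 1.0)
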