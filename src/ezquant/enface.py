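"""En face EZ–RPE thickness maps and the central-subfield (CSF) mask.

The EZ thickness at en face cell (b, a) is the axial distance between the
EZ inner border and the RPE inner border in micrometres; cells where the EZ
is undefined (candidate defect) map to 0 and appear dark.  The CSF is the
central 1 mm diameter disc of the ETDRS macular grid (area pi * 0.25 ~
0.785 mm^2), placed at the fovea; membership is decided by the pixel-center
test so that areas are exact pixel counts times the pixel area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScanGeometry

__all__ = ["EnFaceMap", "CSFMask", "thickness_map", "csf_mask", "CSF_DIAMETER_MM"]

#: ETDRS central subfield diameter
CSF_DIAMETER_MM = 1.0
#: exact disc area implied by the CSF diameter (mm^2)
CSF_DISC_AREA_MM2 = float(np.pi * (CSF_DIAMETER_MM / 2.0) ** 2)


@dataclass
class EnFaceMap:
    """EZ thickness per (B-scan, A-scan) cell on the calibrated grid."""

    thickness_um: np.ndarray
    valid_mask: np.ndarray
    pixel_dims_mm: tuple[float, float]  # (lateral pitch, B-scan spacing)
    fovea_center: tuple[float, float]  # (b, a) grid position
    geometry: ScanGeometry


@dataclass
class CSFMask:
    """Central-subfield membership grid."""

    mask: np.ndarray
    center: tuple[float, float]  # (b, a) grid position
    diameter_mm: float
    partial: bool  # disc clipped by the field edge
    pixel_area_mm2: float

    @property
    def area_mm2(self) -> float:
        """Rasterized mask area (pixel count x pixel area)."""
        return float(self.mask.sum() * self.pixel_area_mm2)


def thickness_map(
    boundaries,
    geometry: ScanGeometry,
    fovea_center: tuple[float, float] | None = None,
    confidence_threshold: float = 0.0,
) -> EnFaceMap:
    """Build the en face EZ–RPE thickness map from per-B-scan boundaries.

    Parameters
    ----------
    boundaries
        Either a :class:`~ezquant.layer_seg.VolumeBoundaries` or a list of
        per-B-scan :class:`~ezquant.layer_seg.BoundaryPair`, one per B-scan.
    geometry
        Scan geometry; supplies the axial µm/pixel calibration.
    fovea_center
        (b, a) grid position of the fovea; defaults to the field center
        (the acquisition protocol centers scans on the fovea).
    confidence_threshold
        Cells with segmentation confidence below this (where the EZ is
        defined) are excluded from ``valid_mask``.

    Returns
    -------
    EnFaceMap
        ``thickness_um`` is ``(rpe - ez) * axial_um_per_px`` where the EZ is
        defined and 0 elsewhere (the dark-pixel convention for defects).
    """
    if isinstance(boundaries, (list, tuple)):
        ez = np.stack([b.ez_inner_depth for b in boundaries])
        rpe = np.stack([b.rpe_inner_depth for b in boundaries])
        conf = np.stack([b.confidence for b in boundaries])
        rpe_det = np.stack([b.rpe_detected for b in boundaries])
    else:
        ez, rpe = boundaries.ez_inner_depth, boundaries.rpe_inner_depth
        conf, rpe_det = boundaries.confidence, boundaries.rpe_detected
    if ez.shape != geometry.en_face_shape:
        raise ValueError(
            f"boundary grid {ez.shape} does not match geometry "
            f"{geometry.en_face_shape}"
        )
    ez_defined = np.isfinite(ez)
    with np.errstate(invalid="ignore"):
        thick = np.where(ez_defined, (rpe - ez) * geometry.axial_um_per_px, 0.0)
    thick = np.nan_to_num(np.maximum(thick, 0.0))
    valid = np.asarray(rpe_det, dtype=bool) & ~(
        ez_defined & (conf < confidence_threshold)
    )
    if fovea_center is None:
        fovea_center = geometry.center_grid
    return EnFaceMap(
        thickness_um=thick.astype(np.float64),
        valid_mask=valid,
        pixel_dims_mm=(geometry.ascan_pitch_mm, geometry.bscan_pitch_mm),
        fovea_center=fovea_center,
        geometry=geometry,
    )


def csf_mask(
    geometry: ScanGeometry,
    fovea_center: tuple[float, float] | None = None,
    diameter_mm: float = CSF_DIAMETER_MM,
) -> CSFMask:
    """Central-subfield disc mask by the pixel-center membership test.

    A pixel belongs to the CSF iff its center lies within ``diameter_mm/2``
    of the fovea center in physical (mm) coordinates.  If the disc would be
    clipped by the field edge the ``partial`` warning flag is set.
    """
    if fovea_center is None:
        fovea_center = geometry.center_grid
    fb, fa = fovea_center
    if not (0 <= fb < geometry.n_bscans and 0 <= fa < geometry.n_ascans):
        raise ValueError(f"fovea center {fovea_center} outside the grid")
    px, py = geometry.ascan_pitch_mm, geometry.bscan_pitch_mm
    cx, cy = (fa + 0.5) * px, (fb + 0.5) * py
    x = (np.arange(geometry.n_ascans) + 0.5) * px
    y = (np.arange(geometry.n_bscans) + 0.5) * py
    r = diameter_mm / 2.0
    mask = (x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2 <= r**2
    partial = (
        cx - r < 0
        or cy - r < 0
        or cx + r > geometry.lateral_extent_mm
        or cy + r > geometry.bscan_extent_mm
    )
    return CSFMask(
        mask=mask,
        center=(float(fb), float(fa)),
        diameter_mm=diameter_mm,
        partial=bool(partial),
        pixel_area_mm2=geometry.en_face_pixel_area_mm2,
    )
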