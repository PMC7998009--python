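"""Scan geometry: device dialects, grid dimensions and physical calibration.

An SD-OCT macular volume is a stack of ``n_bscans`` cross-sectional B-scans,
each composed of ``n_ascans`` axial depth profiles (A-scans) of ``n_axial``
pixels.  Two acquisition dialects are supported:

* ``cirrus6mm`` — Zeiss Cirrus macular cube, 512 A-scans x 128 B-scans over a
  6 mm x 6 mm field.
* ``spectralis20deg`` — Heidelberg Spectralis, 512 A-scans x 97 B-scans over a
  20 x 20 degree field.  The physical extent in mm depends on the eye; the
  conversion factor is configurable and defaults to the emmetropic schematic
  eye (0.291 mm/degree).

En face coordinates: pixel ``(b, a)`` (B-scan row, A-scan column) has its
center at ``x = (a + 0.5) * ascan_pitch_mm``, ``y = (b + 0.5) * bscan_pitch_mm``
from the field corner.  Depth index 0 is the innermost (vitreous) row; all
grids are 0-based with half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ScanGeometry",
    "make_geometry",
    "DIALECTS",
    "SPECTRALIS_MM_PER_DEGREE",
    "DEFAULT_N_AXIAL",
    "DEFAULT_AXIAL_UM_PER_PX",
]

#: mm per degree of visual angle for the emmetropic schematic eye
SPECTRALIS_MM_PER_DEGREE = 0.291
#: axial pixels per A-scan (device-typical; only relative band depths matter)
DEFAULT_N_AXIAL = 496
#: axial sampling in micrometres per pixel
DEFAULT_AXIAL_UM_PER_PX = 3.9

DIALECTS = ("cirrus6mm", "spectralis20deg")


class GeometryError(ValueError):
    """Raised for unknown dialects or inconsistent calibration."""


@dataclass(frozen=True)
class ScanGeometry:
    """Grid dimensions and physical calibration of one SD-OCT volume."""

    dialect: str
    n_ascans: int
    n_bscans: int
    n_axial: int
    lateral_extent_mm: float
    bscan_extent_mm: float
    axial_um_per_px: float

    def __post_init__(self) -> None:
        if self.n_ascans <= 0 or self.n_bscans <= 0 or self.n_axial <= 0:
            raise GeometryError("grid dimensions must be positive")
        if self.lateral_extent_mm <= 0 or self.bscan_extent_mm <= 0:
            raise GeometryError("physical extents must be positive")
        if self.axial_um_per_px <= 0:
            raise GeometryError("axial calibration must be positive")

    @property
    def ascan_pitch_mm(self) -> float:
        """Lateral spacing between adjacent A-scan centers (mm)."""
        return self.lateral_extent_mm / self.n_ascans

    @property
    def bscan_pitch_mm(self) -> float:
        """Spacing between adjacent B-scans (mm)."""
        return self.bscan_extent_mm / self.n_bscans

    @property
    def en_face_pixel_area_mm2(self) -> float:
        """Area of one en face grid cell (mm^2)."""
        return self.ascan_pitch_mm * self.bscan_pitch_mm

    @property
    def en_face_shape(self) -> tuple[int, int]:
        """(n_bscans, n_ascans) — shape of en face maps."""
        return (self.n_bscans, self.n_ascans)

    @property
    def center_grid(self) -> tuple[float, float]:
        """Grid position (b, a) of the field center, in index coordinates."""
        return (self.n_bscans / 2.0 - 0.5, self.n_ascans / 2.0 - 0.5)


def make_geometry(
    dialect: str,
    spectralis_mm_per_degree: float = SPECTRALIS_MM_PER_DEGREE,
    n_axial: int = DEFAULT_N_AXIAL,
    axial_um_per_px: float = DEFAULT_AXIAL_UM_PER_PX,
) -> ScanGeometry:
    """Build a fully calibrated :class:`ScanGeometry` for a device dialect.

    Parameters
    ----------
    dialect
        ``"cirrus6mm"`` or ``"spectralis20deg"``.
    spectralis_mm_per_degree
        Degree-to-mm conversion used only for the Spectralis dialect.
    n_axial, axial_um_per_px
        Axial sampling; configurable because only relative band depths are
        used downstream.

    Raises
    ------
    GeometryError
        If ``dialect`` is not a supported value.
    """
    if dialect == "cirrus6mm":
        return ScanGeometry(
            dialect="cirrus6mm",
            n_ascans=512,
            n_bscans=128,
            n_axial=n_axial,
            lateral_extent_mm=6.0,
            bscan_extent_mm=6.0,
            axial_um_per_px=axial_um_per_px,
        )
    if dialect == "spectralis20deg":
        extent = 20.0 * spectralis_mm_per_degree
        return ScanGeometry(
            dialect="spectralis20deg",
            n_ascans=512,
            n_bscans=97,
            n_axial=n_axial,
            lateral_extent_mm=extent,
            bscan_extent_mm=extent,
            axial_um_per_px=axial_um_per_px,
        )
    raise GeometryError(
        f"unknown dialect {dialect!r}; expected one of {DIALECTS}"
    )
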