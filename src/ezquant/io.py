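"""Readers and writers for volumes, maps, masks and boundary tables.

Volumes travel as multi-frame TIFF (one frame per B-scan) or as a minimal
multi-frame DICOM secondary-capture object; en face maps as 32-bit TIFF
with an 8-bit PNG preview; masks as PNG; ground truth as JSON + PNG
sidecars; boundaries as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .enface import EnFaceMap
from .geometry import ScanGeometry
from .layer_seg import VolumeBoundaries
from .oct_synth import GroundTruth, OCTVolume

__all__ = [
    "write_volume_tiff",
    "read_volume_tiff",
    "write_volume_dicom",
    "read_volume_dicom",
    "write_ground_truth",
    "read_ground_truth",
    "write_enface_map",
    "write_mask_png",
    "read_mask_png",
    "boundaries_to_csv",
]


def _geometry_meta(geometry: ScanGeometry) -> dict:
    return {
        "dialect": geometry.dialect,
        "n_ascans": geometry.n_ascans,
        "n_bscans": geometry.n_bscans,
        "n_axial": geometry.n_axial,
        "lateral_extent_mm": geometry.lateral_extent_mm,
        "bscan_extent_mm": geometry.bscan_extent_mm,
        "axial_um_per_px": geometry.axial_um_per_px,
    }


def _geometry_from_meta(meta: dict) -> ScanGeometry:
    return ScanGeometry(**meta)


def write_volume_tiff(volume: OCTVolume, path) -> None:
    """Multi-frame float32 TIFF, one frame per B-scan; geometry in the
    image description tag."""
    tifffile.imwrite(
        path,
        volume.data.astype(np.float32),
        description=json.dumps(_geometry_meta(volume.geometry)),
    )


def read_volume_tiff(path) -> OCTVolume:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    return OCTVolume(data=data, geometry=_geometry_from_meta(meta))


def write_volume_dicom(volume: OCTVolume, path) -> None:
    """Minimal multi-frame DICOM (secondary-capture style, 16-bit)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OPT"
    ds.SeriesDescription = json.dumps(_geometry_meta(volume.geometry))
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = volume.geometry.n_bscans
    ds.Rows = volume.geometry.n_axial
    ds.Columns = volume.geometry.n_ascans
    data = volume.data.astype(np.float64)
    lo, hi = float(data.min()), float(data.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    ds.RescaleIntercept = lo
    ds.RescaleSlope = 1.0 / scale
    ds.PixelData = ((data - lo) * scale).round().astype(np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_volume_dicom(path) -> OCTVolume:
    import pydicom

    ds = pydicom.dcmread(path)
    geom = _geometry_from_meta(json.loads(ds.SeriesDescription))
    data = ds.pixel_array.astype(np.float32)
    data = data * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
    return OCTVolume(
        data=data.reshape(geom.n_bscans, geom.n_axial, geom.n_ascans), geometry=geom
    )


def write_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, bool) * np.uint8(255))).save(path)


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 0


def write_ground_truth(truth: GroundTruth, directory, stem: str = "truth") -> None:
    """JSON sidecar plus PNG defect mask."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "true_defect_area_mm2": truth.true_defect_area_mm2,
        "gradable": truth.gradable,
        "blocked_fraction": truth.blocked_fraction,
    }
    (directory / f"{stem}.json").write_text(json.dumps(payload, indent=2))
    write_mask_png(truth.defect_mask, directory / f"{stem}_defect_mask.png")
    np.savez_compressed(
        directory / f"{stem}_boundaries.npz",
        ez_inner_depth=truth.ez_inner_depth,
        rpe_inner_depth=truth.rpe_inner_depth,
    )


def read_ground_truth(directory, stem: str = "truth") -> dict:
    directory = Path(directory)
    payload = json.loads((directory / f"{stem}.json").read_text())
    payload["defect_mask"] = read_mask_png(directory / f"{stem}_defect_mask.png")
    with np.load(directory / f"{stem}_boundaries.npz") as npz:
        payload["ez_inner_depth"] = npz["ez_inner_depth"]
        payload["rpe_inner_depth"] = npz["rpe_inner_depth"]
    return payload


def write_enface_map(enface_map: EnFaceMap, tiff_path, png_path=None) -> None:
    """32-bit TIFF of the thickness map plus optional 8-bit preview PNG."""
    tifffile.imwrite(
        tiff_path,
        enface_map.thickness_um.astype(np.float32),
        description=json.dumps(
            {
                "pixel_dims_mm": list(enface_map.pixel_dims_mm),
                "fovea_center": list(enface_map.fovea_center),
                **_geometry_meta(enface_map.geometry),
            }
        ),
    )
    if png_path is not None:
        t = enface_map.thickness_um
        hi = float(t.max()) or 1.0
        Image.fromarray((255 * t / hi).round().astype(np.uint8)).save(png_path)


def boundaries_to_csv(boundaries: VolumeBoundaries, path) -> None:
    """Long-format CSV: (bscan, ascan, ez_depth, rpe_depth, confidence)."""
    n_b, n_a = boundaries.ez_inner_depth.shape
    b, a = np.meshgrid(np.arange(n_b), np.arange(n_a), indexing="ij")
    pd.DataFrame(
        {
            "bscan": b.ravel(),
            "ascan": a.ravel(),
            "ez_depth": boundaries.ez_inner_depth.ravel(),
            "rpe_depth": boundaries.rpe_inner_depth.ravel(),
            "confidence": boundaries.confidence.ravel(),
        }
    ).to_csv(path, index=False)
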