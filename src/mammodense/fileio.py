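"""Image and manifest I/O: DICOM, PNG/TIFF, masks and cohort export.

DICOM pixel spacing is stored in millimetres per the standard and converted
to centimetres here; for PNG/TIFF the spacing must come from the manifest or
the pipeline configuration.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .segmentation import MammogramImage
from .synthetic import SyntheticSubject

__all__ = [
    "read_image",
    "read_mask",
    "write_png",
    "write_mask_png",
    "write_dicom",
    "write_cohort",
    "read_manifest",
]

MANIFEST_COLUMNS = ["path", "mask_path", "subject_id", "laterality", "timepoint",
                    "pixel_spacing_cm"]


def _read_dicom(path: Path, spacing_cm: float | None):
    import pydicom

    ds = pydicom.dcmread(path)
    pixels = ds.pixel_array
    spacing = None
    for tag in ("PixelSpacing", "ImagerPixelSpacing"):
        val = getattr(ds, tag, None)
        if val:
            spacing = float(val[0]) / 10.0  # mm -> cm; metadata wins over config
            break
    if spacing is None:
        spacing = spacing_cm
    return pixels, spacing


def read_image(
    path: str | os.PathLike,
    pixel_spacing_cm: float | None = None,
    laterality: str = "L",
    timepoint: str = "entry",
    subject_id: str = "",
) -> MammogramImage:
    """Read a mammogram from DICOM, PNG or TIFF.

    DICOM pixel-spacing metadata takes precedence over the supplied
    ``pixel_spacing_cm``; for raster formats the argument is required.
    Deeper-than-8-bit data are kept as read; normalize with
    :func:`mammodense.segmentation.to_uint8` once the mask is available.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in (".dcm", ".dicom"):
            pixels, spacing = _read_dicom(path, pixel_spacing_cm)
        else:
            pixels = np.asarray(Image.open(path).convert("I"))
            if pixels.max() <= 255:
                pixels = pixels.astype(np.uint8)
            spacing = pixel_spacing_cm
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - depends on corrupt input
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if spacing is None:
        raise ValueError(f"no pixel spacing for {path}: supply pixel_spacing_cm")
    return MammogramImage(pixels=pixels, pixel_spacing_cm=spacing,
                          laterality=laterality, timepoint=timepoint,
                          subject_id=subject_id)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Binary breast mask from an image file (any nonzero pixel = breast)."""
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 0


def write_png(pixels: np.ndarray, path: str | os.PathLike) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="L").save(path)


def write_mask_png(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary map as an 8-bit PNG (white = true, e.g. dense tissue)."""
    write_png(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8), path)


def write_dicom(image: MammogramImage, path: str | os.PathLike) -> None:
    """Write a minimal secondary-capture DICOM with pixel-spacing metadata."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.PatientID = image.subject_id or "SYN"
    ds.ImageLaterality = image.laterality
    ds.SeriesDescription = image.timepoint
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = image.pixels.shape
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [image.pixel_spacing_cm * 10.0] * 2  # cm -> mm
    ds.PixelData = np.ascontiguousarray(image.pixels, dtype=np.uint8).tobytes()
    ds.save_as(path, enforce_file_format=True)


def write_cohort(subjects: list[SyntheticSubject], outdir: str | os.PathLike,
                 dicom: bool = False) -> pd.DataFrame:
    """Write a synthetic cohort as images + masks + a sidecar CSV manifest.

    Returns the manifest (also written to ``manifest.csv``): one row per
    image with path, mask path, identity, pixel spacing and the generator's
    ground-truth overall PD.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        for slot, img in s.images.items():
            stem = f"{s.subject_id}_{slot}"
            suffix = ".dcm" if dicom else ".png"
            img_path = outdir / f"{stem}{suffix}"
            mask_path = outdir / f"{stem}_mask.png"
            if dicom:
                write_dicom(img, img_path)
            else:
                write_png(img.pixels, img_path)
            write_mask_png(s.truths[slot].mask, mask_path)
            rows.append({
                "path": img_path.name, "mask_path": mask_path.name,
                "subject_id": s.subject_id, "laterality": img.laterality,
                "timepoint": img.timepoint,
                "pixel_spacing_cm": img.pixel_spacing_cm,
                "age_entry": s.age_entry,
                "true_overall_pd": s.truths[slot].true_overall_pd,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate an input manifest CSV."""
    path = Path(path)
    manifest = pd.read_csv(path)
    if manifest.empty:
        raise ValueError(f"empty manifest: {path}")
    missing = [c for c in ("path", "subject_id", "laterality", "timepoint")
               if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    return manifest
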