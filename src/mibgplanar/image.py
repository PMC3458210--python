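"""Planar scintigram container and file I/O.

A planar anterior MIBG acquisition is a single 2-D count matrix (typically
256 x 256) taken at two time points: an *early* image ~15 min after tracer
administration and a *delayed* image ~4 h later.  This module defines the
in-memory container for one such image and readers/writers for two on-disk
representations: a plain whitespace-delimited matrix with a small metadata
header, and a DICOM secondary-capture object (via :mod:`pydicom`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

EARLY = "early"
DELAYED = "delayed"

#: default acquisition offsets after tracer administration, minutes
DEFAULT_OFFSET_MIN = {EARLY: 15.0, DELAYED: 240.0}

#: default pixel spacing, mm per pixel, for a 256 x 256 anterior thorax frame
#: (the 60 x 70 px oval cardiac ROI corresponds to ~85 x 100 mm, i.e. ~1.42 mm/px)
DEFAULT_PIXEL_SPACING_MM = 1.42


@dataclass
class PlanarImage:
    """A single anterior planar count image.

    Parameters
    ----------
    counts
        2-D non-negative matrix of counts per pixel.  Integer for measured
        (Poisson) data; real-valued for expectation (noise-free) images or
        after rescaling.
    phase
        ``"early"`` or ``"delayed"``.
    acquisition_offset_min
        Minutes between tracer administration and acquisition start.
    pixel_spacing_mm
        Physical size of one pixel, mm.
    """

    counts: np.ndarray
    phase: str
    acquisition_offset_min: float = field(default=None)  # type: ignore[assignment]
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError(f"counts must be a 2-D matrix, got ndim={self.counts.ndim}")
        if self.phase not in (EARLY, DELAYED):
            raise ValueError(f"phase must be 'early' or 'delayed', got {self.phase!r}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.acquisition_offset_min is None:
            self.acquisition_offset_min = DEFAULT_OFFSET_MIN[self.phase]
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]

    def scaled(self, factor: float) -> "PlanarImage":
        """Return a copy with counts multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, counts=self.counts * factor)


# ---------------------------------------------------------------------------
# plain-text matrix format
# ---------------------------------------------------------------------------

def write_matrix(path: str | Path, image: PlanarImage) -> None:
    """Write a planar image as a whitespace-delimited matrix.

    Metadata (phase, acquisition offset, pixel spacing) is stored in ``#``
    header comment lines so a pair of files is self-describing.
    """
    header = json.dumps(
        {
            "phase": image.phase,
            "acquisition_offset_min": image.acquisition_offset_min,
            "pixel_spacing_mm": image.pixel_spacing_mm,
        }
    )
    fmt = "%d" if np.issubdtype(image.counts.dtype, np.integer) else "%.10g"
    np.savetxt(path, image.counts, fmt=fmt, header=header)


def read_matrix(path: str | Path) -> PlanarImage:
    """Read a planar image written by :func:`write_matrix`."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        try:
            meta = json.loads(first[1:].strip())
        except json.JSONDecodeError as exc:
            raise ValueError(f"unparseable metadata header in {path}") from exc
    if "phase" not in meta:
        raise ValueError(f"{path}: missing 'phase' in metadata header")
    counts = np.loadtxt(path)
    if np.allclose(counts, np.round(counts)):
        counts = counts.astype(np.int64)
    return PlanarImage(
        counts=counts,
        phase=meta["phase"],
        acquisition_offset_min=meta.get("acquisition_offset_min"),
        pixel_spacing_mm=meta.get("pixel_spacing_mm", DEFAULT_PIXEL_SPACING_MM),
    )


# ---------------------------------------------------------------------------
# DICOM secondary capture
# ---------------------------------------------------------------------------

def write_dicom(path: str | Path, image: PlanarImage) -> None:
    """Write the image as an uncompressed monochrome DICOM secondary capture.

    Counts are stored as unsigned 16-bit integers; real-valued count matrices
    are rejected (round explicitly first if that is acceptable).
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    counts = image.counts
    if not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("DICOM export requires integer counts; round first if intended")
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("counts exceed 16-bit DICOM pixel range")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    ds.SeriesDescription = f"MIBG planar {image.phase}"
    ds.ImageComments = json.dumps(
        {"phase": image.phase, "acquisition_offset_min": image.acquisition_offset_min}
    )
    ds.Rows, ds.Columns = counts.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [image.pixel_spacing_mm, image.pixel_spacing_mm]
    ds.PixelData = counts.astype("<u2").tobytes()
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


def read_dicom(path: str | Path) -> PlanarImage:
    """Read a planar image from a DICOM file written by :func:`write_dicom`."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    meta = {}
    if getattr(ds, "ImageComments", None):
        try:
            meta = json.loads(ds.ImageComments)
        except json.JSONDecodeError:
            meta = {}
    phase = meta.get("phase")
    if phase is None:
        desc = getattr(ds, "SeriesDescription", "") or ""
        phase = DELAYED if DELAYED in desc.lower() else EARLY
    spacing = DEFAULT_PIXEL_SPACING_MM
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    return PlanarImage(
        counts=ds.pixel_array.astype(np.int64),
        phase=phase,
        acquisition_offset_min=meta.get("acquisition_offset_min"),
        pixel_spacing_mm=spacing,
    )
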