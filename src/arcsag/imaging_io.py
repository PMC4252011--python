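"""Portal-image I/O, coordinate conventions and arc-series assembly.

Coordinate conventions used throughout the package
--------------------------------------------------

* Image arrays are indexed ``pixels[row, col]``.  Pixel centres sit at
  integer (row, col) positions; fractional coordinates are allowed
  everywhere for sub-pixel work.
* The detector plane carries a metric frame (mm) with ``+x`` along
  increasing column index (cross-plane) and ``+y`` along *decreasing* row
  index (in-plane, toward the gun).  ``origin_mm`` is the detector-plane
  (x, y) of pixel ``(0, 0)``; by default the beam axis pierces the
  geometric panel centre.
* All public results are expressed at the isocentre plane: detector-plane
  millimetres divided by the magnification ``sdd_mm / SAD`` with the
  source-to-axis distance SAD = 1000 mm.
* Gantry angles follow the IEC 61217 convention and are normalised to
  (-180, 180]; gantry 0 points the beam straight down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset

from .errors import (
    ConsistencyError,
    CoverageError,
    FormatError,
    MetadataError,
    ReferenceFrameError,
)

SAD_MM = 1000.0
"""Source-to-axis distance of the supported machines (mm)."""

SUPPORTED_PANEL_SHAPES = {(384, 512), (768, 1024)}
"""(rows, cols) of the active grids of the supported imager models."""

#: Frame with the smallest |gantry angle| must lie within this of zero.
REFERENCE_TOLERANCE_DEG = 2.0


def wrap_angle_deg(angle):
    """Normalise an angle in degrees onto the IEC interval (-180, 180].

    Works on scalars and arrays; idempotent; maps [0, 360) bijectively.
    """
    wrapped = np.mod(angle, 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class PlanePoint:
    """A point in the isocentre plane: x = cross-plane, y = in-plane (mm)."""

    x_mm: float
    y_mm: float

    def __post_init__(self):
        if not (math.isfinite(self.x_mm) and math.isfinite(self.y_mm)):
            raise ValueError("PlanePoint coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm])


@dataclass
class BeamImage:
    """One portal image plus the acquisition geometry needed to analyse it."""

    pixels: np.ndarray
    gantry_angle_deg: float
    collimator_angle_deg: float
    sdd_mm: float
    pixel_spacing_mm: tuple[float, float]  # (row, col)
    acquisition_mode: str = "integrated"  # {"cine", "integrated"}
    frame_index: int = 0
    origin_mm: tuple[float, float] | None = None  # detector (x, y) of pixel (0, 0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise FormatError("pixels must be a 2-D intensity grid")
        if self.pixels.shape not in SUPPORTED_PANEL_SHAPES:
            raise FormatError(
                f"unsupported panel format {self.pixels.shape}; expected one of "
                f"{sorted(SUPPORTED_PANEL_SHAPES)}"
            )
        dr, dc = self.pixel_spacing_mm
        if dr <= 0 or dc <= 0:
            raise ValueError("pixel_spacing_mm must be positive in both axes")
        if self.sdd_mm <= SAD_MM:
            raise ValueError(f"sdd_mm = {self.sdd_mm} must exceed SAD = {SAD_MM}")
        if self.acquisition_mode not in ("cine", "integrated"):
            raise ValueError(f"unknown acquisition_mode {self.acquisition_mode!r}")
        self.gantry_angle_deg = wrap_angle_deg(self.gantry_angle_deg)
        if self.origin_mm is None:
            rows, cols = self.pixels.shape
            self.origin_mm = (-(cols - 1) / 2.0 * dc, (rows - 1) / 2.0 * dr)

    # -- coordinate transforms -------------------------------------------
    @property
    def magnification(self) -> float:
        return self.sdd_mm / SAD_MM

    def detector_xy(self, row, col):
        """Detector-plane (x, y) in mm of fractional pixel coordinates."""
        x0, y0 = self.origin_mm
        dr, dc = self.pixel_spacing_mm
        return x0 + np.asarray(col) * dc, y0 - np.asarray(row) * dr

    def pixel_from_detector(self, x_mm, y_mm):
        """Inverse of :meth:`detector_xy` -> fractional (row, col)."""
        x0, y0 = self.origin_mm
        dr, dc = self.pixel_spacing_mm
        return (y0 - np.asarray(y_mm)) / dr, (np.asarray(x_mm) - x0) / dc

    def pixel_from_iso(self, x_mm, y_mm):
        """Fractional (row, col) of an isocentre-plane position."""
        m = self.magnification
        return self.pixel_from_detector(np.asarray(x_mm) * m, np.asarray(y_mm) * m)


def to_isocentre_mm(pixel_row, pixel_col, image: BeamImage) -> PlanePoint:
    """Map fractional pixel coordinates to the isocentre plane.

    Detector-plane offsets from the beam-axis reference point are divided by
    the magnification SDD/SAD so that 1.5 mm on the panel at SDD 1500 mm is
    reported as 1.0 mm at the isocentre.
    """
    x_det, y_det = image.detector_xy(pixel_row, pixel_col)
    scale = SAD_MM / image.sdd_mm
    return PlanePoint(float(x_det) * scale, float(y_det) * scale)


# ---------------------------------------------------------------------------
# DICOM reading
# ---------------------------------------------------------------------------

_MANDATORY_TAGS = {
    "GantryAngle": "gantry angle (300A,011E)",
    "BeamLimitingDeviceAngle": "collimator angle (300A,0120)",
    "RTImageSID": "source-to-detector distance (3002,0026)",
    "ImagePlanePixelSpacing": "image plane pixel spacing (3002,0011)",
}


def read_beam_image(source) -> BeamImage:
    """Read a single-frame DICOM RT portal image into a :class:`BeamImage`.

    Pixel intensities are taken as stored (dark-field / flood-field
    correction is assumed to have been applied by the acquisition system).
    The gantry angle is normalised to the IEC interval (-180, 180].

    Raises
    ------
    MetadataError
        if a mandatory geometry tag is missing (the message names the tag).
    FormatError
        if the file holds no usable single image frame.
    """
    try:
        ds = pydicom.dcmread(source)
    except Exception as exc:  # pydicom raises several flavours
        raise FormatError(f"not a readable DICOM file: {exc}") from exc

    if "PixelData" not in ds:
        raise FormatError("DICOM object carries no PixelData; not an image")

    for attr, label in _MANDATORY_TAGS.items():
        if getattr(ds, attr, None) is None:
            raise MetadataError(f"missing mandatory metadata: {label}")

    pixels = ds.pixel_array
    if pixels.ndim != 2:
        raise FormatError(f"expected a single frame, got array of shape {pixels.shape}")

    spacing = [float(v) for v in ds.ImagePlanePixelSpacing]
    origin = None
    if getattr(ds, "RTImagePosition", None) is not None:
        pos = [float(v) for v in ds.RTImagePosition]
        origin = (pos[0], pos[1])

    mode = "integrated"
    image_type = list(getattr(ds, "ImageType", []) or [])
    if any(str(v).upper() == "CINE" for v in image_type):
        mode = "cine"

    return BeamImage(
        pixels=pixels.astype(float),
        gantry_angle_deg=float(ds.GantryAngle),
        collimator_angle_deg=float(ds.BeamLimitingDeviceAngle),
        sdd_mm=float(ds.RTImageSID),
        pixel_spacing_mm=(spacing[0], spacing[1]),
        acquisition_mode=mode,
        frame_index=int(getattr(ds, "InstanceNumber", 0) or 0),
        origin_mm=origin,
    )


# ---------------------------------------------------------------------------
# Arc series
# ---------------------------------------------------------------------------


@dataclass
class ArcSeries:
    """An ordered arc of portal images with a gantry-zero reference frame."""

    images: list[BeamImage]
    direction: str  # {"CW", "CCW"}
    collimator_setting_deg: float
    replicate_id: int = 1
    reference_index: int = field(default=0)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([im.gantry_angle_deg for im in self.images])

    @property
    def reference_image(self) -> BeamImage:
        return self.images[self.reference_index]

    @property
    def sdd0_mm(self) -> float:
        return self.reference_image.sdd_mm


def angular_coverage_deg(angles_deg: Sequence[float]) -> float:
    """Coverage of a set of IEC angles: 360 minus the largest angular gap."""
    a = np.sort(np.mod(np.asarray(angles_deg, dtype=float), 360.0))
    if a.size < 2:
        return 0.0
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    return float(360.0 - gaps.max())


def load_arc_series(
    sources: Iterable,
    direction: str = "CW",
    collimator_setting_deg: float | None = None,
    replicate_id: int = 1,
    *,
    reference_tolerance_deg: float = REFERENCE_TOLERANCE_DEG,
) -> ArcSeries:
    """Assemble an :class:`ArcSeries` from DICOM paths or BeamImages.

    Images are sorted by acquisition order (``frame_index``); the frame with
    the smallest absolute gantry angle becomes the reference, ties broken by
    acquisition order.  Duplicate-angle frames are retained.
    """
    images: list[BeamImage] = []
    for src in sources:
        if isinstance(src, BeamImage):
            images.append(src)
        else:
            images.append(read_beam_image(str(Path(src))))
    if len(images) < 3:
        raise CoverageError(f"need at least 3 images, got {len(images)}")

    images.sort(key=lambda im: im.frame_index)  # stable: preserves input order on ties

    angles = np.array([im.gantry_angle_deg for im in images])
    if angular_coverage_deg(angles) <= 180.0:
        raise CoverageError(
            f"arc spans only {angular_coverage_deg(angles):.1f} deg; need > 180"
        )

    colls = {im.collimator_angle_deg for im in images}
    if len(colls) > 1:
        raise ConsistencyError(f"mixed collimator angles in one series: {sorted(colls)}")
    modes = {im.acquisition_mode for im in images}
    if len(modes) > 1:
        raise ConsistencyError(f"mixed acquisition modes in one series: {sorted(modes)}")

    ref = int(np.argmin(np.abs(angles)))  # argmin returns the first minimum
    if abs(angles[ref]) > reference_tolerance_deg:
        raise ReferenceFrameError(
            f"closest frame to gantry zero is at {angles[ref]:.2f} deg "
            f"(> {reference_tolerance_deg} deg tolerance)"
        )

    if collimator_setting_deg is None:
        collimator_setting_deg = images[0].collimator_angle_deg

    return ArcSeries(
        images=images,
        direction=direction,
        collimator_setting_deg=float(collimator_setting_deg),
        replicate_id=replicate_id,
        reference_index=ref,
    )


# ---------------------------------------------------------------------------
# DICOM writing (used by the simulator; kept here with the reader so the
# round-trip convention lives in one module)
# ---------------------------------------------------------------------------


def write_beam_image(image: BeamImage, path) -> Path:
    """Write a BeamImage as a DICOM RT Image file readable by read_beam_image."""
    path = Path(path)
    ds = Dataset()
    ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.481.1"  # RT Image Storage
    ds.SOPInstanceUID = pydicom.uid.generate_uid()
    ds.Modality = "RTIMAGE"
    ds.ImageType = ["DERIVED", "SECONDARY", "PORTAL", image.acquisition_mode.upper()]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = image.pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.GantryAngle = float(np.mod(image.gantry_angle_deg, 360.0))
    ds.BeamLimitingDeviceAngle = float(image.collimator_angle_deg)
    ds.RTImageSID = float(image.sdd_mm)
    ds.RadiationMachineSAD = SAD_MM
    ds.ImagePlanePixelSpacing = [image.pixel_spacing_mm[0], image.pixel_spacing_mm[1]]
    ds.RTImagePosition = [image.origin_mm[0], image.origin_mm[1]]
    ds.InstanceNumber = image.frame_index
    ds.PixelData = (
        np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16).tobytes()
    )

    ds.file_meta = pydicom.dataset.FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = ds.SOPClassUID
    ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    ds.save_as(path, enforce_file_format=True)
    return path
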