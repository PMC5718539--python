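"""Reading and writing DICOM RT Image portal images.

Some EPID exports (notably Elekta iView GT) leave the gantry and
beam-limiting-device angle tags empty even though the standard defines
them.  For such files a strict filename convention ``G<ggg>_C<ccc>.dcm``
(three digits each, IEC 1217 degrees) can supply the missing geometry when
``naming_fallback`` is enabled; malformed names raise rather than guess,
since a silent default or typo would propagate straight into a couch shift.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .geometry import normalize_angle

RT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.1"

VENDORS = ("siemens", "varian", "elekta", "generic")

_VENDOR_NAMES = {
    "siemens": "SIEMENS",
    "varian": "Varian Medical Systems",
    "elekta": "Elekta",
    "generic": "Generic",
}

_FILENAME_RE = re.compile(r"G(\d{3})_C(\d{3})\.dcm", re.IGNORECASE)


class DicomIOError(ValueError):
    pass


class FilenameParseError(DicomIOError):
    pass


@dataclass(frozen=True)
class FilenameGeometry:
    gantry_deg: float
    collimator_deg: float
    vendor: str | None = None


@dataclass
class PortalImage:
    """One acquired (or rendered) portal image plus its geometry.

    pixels : 2-D nonnegative intensity matrix, row 0 at the image top.
    pixel_spacing_mm : (row, column) detector pixel pitch in mm.
    sid_mm / sad_mm : source-to-imager and source-to-axis distances.
    gantry_deg / collimator_deg : IEC 1217 angles, normalised to [0, 360).
    vendor : one of {siemens, varian, elekta, generic}.
    field_size_mm : nominal square field side at the isocenter plane.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    sid_mm: float
    gantry_deg: float
    collimator_deg: float
    vendor: str = "generic"
    sad_mm: float = 1000.0
    field_size_mm: float = 100.0
    source_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DicomIOError("pixels must be a non-empty 2-D matrix")
        if np.isscalar(self.pixel_spacing_mm):
            self.pixel_spacing_mm = (float(self.pixel_spacing_mm),) * 2
        else:
            self.pixel_spacing_mm = tuple(float(s) for s in self.pixel_spacing_mm)
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise DicomIOError("pixel_spacing_mm must be > 0")
        if not (self.sid_mm >= self.sad_mm > 0):
            raise DicomIOError("require sid_mm >= sad_mm > 0")
        self.gantry_deg = normalize_angle(self.gantry_deg)
        self.collimator_deg = normalize_angle(self.collimator_deg)
        if self.vendor not in VENDORS:
            raise DicomIOError(f"unknown vendor {self.vendor!r}")

    @property
    def magnification(self) -> float:
        return self.sid_mm / self.sad_mm

    @property
    def view(self) -> str:
        """'lateral' for horizontal beams (gantry 90/270), else 'AP'."""
        return "lateral" if 45.0 < self.gantry_deg % 180.0 < 135.0 else "AP"


def parse_filename(name: str) -> FilenameGeometry:
    """Parse the documented ``G<ggg>_C<ccc>.dcm`` convention.

    The pattern is matched strictly against the end of the basename; any
    other shape raises :class:`FilenameParseError`.
    """
    base = Path(name).name
    m = _FILENAME_RE.fullmatch(base)
    if m is None:
        raise FilenameParseError(
            f"filename {base!r} does not match the G<ggg>_C<ccc>.dcm convention"
        )
    return FilenameGeometry(
        gantry_deg=normalize_angle(int(m.group(1))),
        collimator_deg=normalize_angle(int(m.group(2))),
    )


def _vendor_from_manufacturer(manufacturer: str | None) -> str:
    if not manufacturer:
        return "generic"
    low = str(manufacturer).lower()
    for v in ("siemens", "varian", "elekta"):
        if v in low:
            return v
    return "generic"


def _angle_tag(ds: Dataset, keyword: str) -> float | None:
    value = getattr(ds, keyword, None)
    if value is None or value == "":
        return None
    return float(value)


def read_portal_image(
    path: str | Path,
    naming_fallback: bool = False,
    field_size_mm: float = 100.0,
    pixel_spacing_mm: tuple[float, float] | None = None,
    sad_mm: float | None = None,
) -> PortalImage:
    """Read one RT Image file into a :class:`PortalImage`.

    Rescale slope/intercept are applied when present.  Empty or missing
    angle tags raise unless ``naming_fallback`` lets :func:`parse_filename`
    supply them.  ``pixel_spacing_mm`` overrides/backstops the
    ImagePlanePixelSpacing tag for files that omit it.
    """
    path = Path(path)
    ds = pydicom.dcmread(str(path))
    if "PixelData" not in ds:
        raise DicomIOError(f"{path.name}: no pixel data")
    pixels = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    pixels = pixels * slope + intercept

    gantry = _angle_tag(ds, "GantryAngle")
    collimator = _angle_tag(ds, "BeamLimitingDeviceAngle")
    if gantry is None or collimator is None:
        if naming_fallback:
            fg = parse_filename(path.name)
            gantry = fg.gantry_deg if gantry is None else gantry
            collimator = fg.collimator_deg if collimator is None else collimator
        else:
            missing = "gantry angle" if gantry is None else "beam limiting device angle"
            raise DicomIOError(f"{path.name}: {missing} unavailable (empty or absent tag)")

    spacing = getattr(ds, "ImagePlanePixelSpacing", None)
    if spacing is None or len(spacing) == 0:
        if pixel_spacing_mm is None:
            raise DicomIOError(f"{path.name}: pixel spacing unavailable; supply it via config")
        spacing = pixel_spacing_mm
    sid = float(getattr(ds, "RTImageSID", 0.0) or 0.0)
    if sid <= 0:
        raise DicomIOError(f"{path.name}: RT Image SID unavailable")
    sad = sad_mm if sad_mm is not None else float(getattr(ds, "RadiationMachineSAD", 1000.0) or 1000.0)

    return PortalImage(
        pixels=pixels,
        pixel_spacing_mm=tuple(float(s) for s in spacing),
        sid_mm=sid,
        sad_mm=sad,
        gantry_deg=gantry,
        collimator_deg=collimator,
        vendor=_vendor_from_manufacturer(getattr(ds, "Manufacturer", None)),
        field_size_mm=field_size_mm,
        source_id=str(path),
    )


def write_portal_image(
    image: PortalImage, path: str | Path, empty_angle_tags: bool = False
) -> Path:
    """Write a PortalImage as an RT Image file (used for synthetic sessions).

    Pixels are stored as unsigned 16-bit with rescale slope 1 / intercept 0.
    ``empty_angle_tags`` emulates the iView GT export quirk of leaving the
    angle tags present but empty.
    """
    path = Path(path)
    px = np.asarray(image.pixels)
    if px.min() < 0 or px.max() > 65535:
        raise DicomIOError("pixels outside the uint16 range")
    stored = np.round(px).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RT_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RT_IMAGE_STORAGE
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTIMAGE"
    ds.Manufacturer = _VENDOR_NAMES[image.vendor]
    if empty_angle_tags:
        ds.GantryAngle = ""
        ds.BeamLimitingDeviceAngle = ""
    else:
        ds.GantryAngle = f"{image.gantry_deg:g}"
        ds.BeamLimitingDeviceAngle = f"{image.collimator_deg:g}"
    ds.ImagePlanePixelSpacing = [f"{s:g}" for s in image.pixel_spacing_mm]
    ds.RTImageSID = f"{image.sid_mm:g}"
    ds.RadiationMachineSAD = f"{image.sad_mm:g}"
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "0"
    ds.Rows, ds.Columns = stored.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = stored.tobytes()
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
    return path
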