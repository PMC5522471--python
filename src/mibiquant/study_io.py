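"""Study containers and I/O for dual-time-point MIBI thyroid scintigraphy.

Domain types
------------
:class:`PlanarImage`
    A single planar gamma-camera frame: a raster of counts plus the
    acquisition metadata the indices need (minutes post-injection, frame
    duration, tracer).
:class:`RoiMask`
    A labelled set of pixels on an image grid (nodule, mirrored background,
    contralateral lobe, thorax background).
:class:`PatientRecord`
    One row of the packaged 20-patient reference cohort: demographics,
    ultrasound/cytology categories, both scintigraphic indices and the
    histological diagnosis.
:class:`StudyBundle`
    The early (+10 min) and late (+60 min) MIBI images of one patient with
    their ROIs, optionally accompanied by a pertechnetate image.

File dialects
-------------
Count images travel as 16-bit PGM or PNG grayscale (the reference dialect:
pixel value == count) or as DICOM; acquisition metadata lives in a sidecar
JSON when the container cannot carry it.  ROIs travel as 8-bit mask rasters
(nonzero == member) or JSON polygons.  The cohort table is a header-keyed
UTF-8 CSV.

Pixel coordinates are 0-based ``(row, col)`` with row 0 at the top of the
image.  Polygon vertices are ``[x, y] == [col, row]`` in pixel-centre
coordinates; a pixel belongs to a polygon when its centre lies inside, with
top/left boundaries inclusive and bottom/right exclusive.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image as _PILImage

__all__ = [
    "Tracer",
    "RoiLabel",
    "Sex",
    "Topography",
    "TiRads",
    "Bethesda",
    "Histology",
    "PlanarImage",
    "RoiMask",
    "PatientRecord",
    "StudyBundle",
    "SchemaError",
    "FormatError",
    "COHORT_COLUMNS",
    "load_cohort_table",
    "cohort_to_frame",
    "read_planar_image",
    "write_planar_image",
    "read_roi_mask",
    "write_roi_mask",
]


class SchemaError(ValueError):
    """A cohort table row or column violates the documented schema."""


class FormatError(ValueError):
    """An image or mask file violates its dialect (e.g. negative counts)."""


class Tracer(str, enum.Enum):
    MIBI = "MIBI"
    PERTECHNETATE = "pertechnetate"


class RoiLabel(str, enum.Enum):
    NODULE = "nodule"
    MIRROR_BACKGROUND = "mirror_background"
    CONTRALATERAL = "contralateral"
    THORAX_BACKGROUND = "thorax_background"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class Topography(str, enum.Enum):
    """Nodule location: left lobe, right lobe, isthmus, or right lobe/isthmus."""

    LL = "LL"
    RL = "RL"
    I = "I"
    RL_I = "RL-I"


class TiRads(str, enum.Enum):
    T3 = "3"
    T4A = "4A"
    T4B = "4B"


class Bethesda(str, enum.Enum):
    III = "III"
    IV = "IV"


class Histology(str, enum.Enum):
    DTC = "DTC"
    BENIGN_ADENOMA = "BenignAdenoma"
    COLLOID_GOITRE = "ColloidGoitre"


@dataclass(frozen=True)
class PlanarImage:
    """A planar scintigraphic frame of raw counts.

    ``counts`` is a 2-D non-negative array.  Acquired frames carry integral
    counts; synthetic noiseless frames and decay-corrected data may be
    real-valued, so floats are accepted in memory while the integer file
    dialects reject them on write/read.
    """

    counts: np.ndarray
    t_acq_min: float
    frame_duration_s: float
    tracer: Tracer = Tracer.MIBI
    injected_activity_MBq: Optional[float] = None
    magnification: float = 1.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.size == 0:
            raise ValueError("counts raster is empty")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite")
        if self.t_acq_min < 0:
            raise ValueError(f"t_acq_min must be >= 0, got {self.t_acq_min}")
        if self.frame_duration_s <= 0:
            raise ValueError(
                f"frame_duration_s must be > 0, got {self.frame_duration_s}"
            )
        if self.injected_activity_MBq is not None and self.injected_activity_MBq <= 0:
            raise ValueError("injected_activity_MBq must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def matrix_size(self) -> tuple[int, int]:
        return tuple(self.counts.shape)  # type: ignore[return-value]

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    def is_integral(self) -> bool:
        return bool(np.issubdtype(self.counts.dtype, np.integer)) or bool(
            np.all(np.equal(np.mod(self.counts, 1), 0))
        )


@dataclass(frozen=True)
class RoiMask:
    """A labelled pixel set on an image grid.

    ``pixels`` is a frozenset of 0-based ``(row, col)`` tuples, all inside
    ``source_grid``.  ``warnings`` carries non-fatal geometry flags (e.g. a
    mirrored background that overlaps its source ROI).
    """

    pixels: frozenset
    label: RoiLabel
    source_grid: tuple[int, int]
    warnings: tuple = ()

    def __post_init__(self) -> None:
        pixels = frozenset((int(r), int(c)) for r, c in self.pixels)
        if not pixels:
            raise ValueError("ROI mask is empty")
        rows, cols = self.source_grid
        for r, c in pixels:
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(
                    f"pixel ({r}, {c}) outside source grid {self.source_grid}"
                )
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "source_grid", (int(rows), int(cols)))
        object.__setattr__(self, "warnings", tuple(self.warnings))

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def to_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row and column index arrays, ordered lexicographically."""
        ordered = sorted(self.pixels)
        rows = np.array([p[0] for p in ordered], dtype=np.intp)
        cols = np.array([p[1] for p in ordered], dtype=np.intp)
        return rows, cols

    def to_mask_array(self) -> np.ndarray:
        out = np.zeros(self.source_grid, dtype=np.uint8)
        rows, cols = self.to_indices()
        out[rows, cols] = 1
        return out

    @classmethod
    def from_mask_array(
        cls, mask: np.ndarray, label: RoiLabel, warnings: tuple = ()
    ) -> "RoiMask":
        mask = np.asarray(mask)
        if mask.ndim != 2:
            raise ValueError("mask array must be 2-D")
        rr, cc = np.nonzero(mask)
        pixels = frozenset(zip(rr.tolist(), cc.tolist()))
        return cls(pixels=pixels, label=label, source_grid=mask.shape, warnings=warnings)


@dataclass(frozen=True)
class PatientRecord:
    """One reference-cohort row; ``is_malignant`` is the histological truth."""

    patient_id: int
    sex: Sex
    age_years: int
    topography: Topography
    nodule_size_mm: int
    tirads: TiRads
    bethesda: Bethesda
    visual_pattern: int
    ri: float
    woind_percent: float
    histology: Histology

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError("age_years must be positive")
        if self.nodule_size_mm <= 0:
            raise ValueError("nodule_size_mm must be positive")

    @property
    def is_malignant(self) -> bool:
        return self.histology is Histology.DTC


@dataclass(frozen=True)
class StudyBundle:
    """Early and late MIBI frames of one patient with their ROIs."""

    early: PlanarImage
    late: PlanarImage
    rois: Mapping[RoiLabel, RoiMask]
    pertechnetate: Optional[PlanarImage] = None

    def __post_init__(self) -> None:
        if self.early.t_acq_min >= self.late.t_acq_min:
            raise ValueError(
                "early acquisition must precede late acquisition "
                f"({self.early.t_acq_min} >= {self.late.t_acq_min} min)"
            )
        rois = dict(self.rois)
        for label, roi in rois.items():
            if roi.label is not label:
                raise ValueError(f"ROI keyed {label} carries label {roi.label}")
            if roi.source_grid != self.early.matrix_size:
                raise ValueError(
                    f"ROI {label.value} grid {roi.source_grid} does not match "
                    f"early image grid {self.early.matrix_size}"
                )
        object.__setattr__(self, "rois", rois)


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "patient_id",
    "sex",
    "age_years",
    "topography",
    "nodule_size_mm",
    "tirads",
    "bethesda",
    "visual_pattern",
    "ri",
    "woind_percent",
    "histology",
)

_FIXTURE_NAME = "cohort_table1.csv"


def packaged_cohort_path() -> Path:
    """Filesystem path of the packaged 20-patient reference cohort CSV."""
    return Path(resources.files("mibiquant.data") / _FIXTURE_NAME)


def _parse_enum(cls, raw, row_idx: int, column: str):
    try:
        return cls(str(raw).strip())
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise SchemaError(
            f"row {row_idx}, column '{column}': value {raw!r} not in {{{allowed}}}"
        ) from None


def _parse_number(kind, raw, row_idx: int, column: str):
    try:
        value = kind(raw)
    except (TypeError, ValueError):
        raise SchemaError(
            f"row {row_idx}, column '{column}': cannot parse {raw!r} as {kind.__name__}"
        ) from None
    return value


def load_cohort_table(source: Optional[object] = None) -> list[PatientRecord]:
    """Load a cohort table; with no argument, the packaged reference cohort.

    Parsing is header-keyed: column order is irrelevant, missing columns and
    out-of-domain values raise :class:`SchemaError` naming the row and column.
    Row order of the file is preserved.
    """
    if source is None:
        source = packaged_cohort_path()
    try:
        frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - surfaced as schema error
        raise SchemaError(f"cannot read cohort table {source!r}: {exc}") from exc

    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    records: list[PatientRecord] = []
    for row_idx, row in enumerate(frame.itertuples(index=False), start=1):
        get = lambda col: getattr(row, col)  # noqa: E731
        try:
            record = PatientRecord(
                patient_id=_parse_number(int, get("patient_id"), row_idx, "patient_id"),
                sex=_parse_enum(Sex, get("sex"), row_idx, "sex"),
                age_years=_parse_number(int, get("age_years"), row_idx, "age_years"),
                topography=_parse_enum(
                    Topography, get("topography"), row_idx, "topography"
                ),
                nodule_size_mm=_parse_number(
                    int, get("nodule_size_mm"), row_idx, "nodule_size_mm"
                ),
                tirads=_parse_enum(TiRads, get("tirads"), row_idx, "tirads"),
                bethesda=_parse_enum(Bethesda, get("bethesda"), row_idx, "bethesda"),
                visual_pattern=_parse_number(
                    int, get("visual_pattern"), row_idx, "visual_pattern"
                ),
                ri=_parse_number(float, get("ri"), row_idx, "ri"),
                woind_percent=_parse_number(
                    float, get("woind_percent"), row_idx, "woind_percent"
                ),
                histology=_parse_enum(Histology, get("histology"), row_idx, "histology"),
            )
        except ValueError as exc:
            if isinstance(exc, SchemaError):
                raise
            raise SchemaError(f"row {row_idx}: {exc}") from exc
        records.append(record)
    return records


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Serialize patient records back to the documented CSV schema."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "sex": [r.sex.value for r in records],
            "age_years": [r.age_years for r in records],
            "topography": [r.topography.value for r in records],
            "nodule_size_mm": [r.nodule_size_mm for r in records],
            "tirads": [r.tirads.value for r in records],
            "bethesda": [r.bethesda.value for r in records],
            "visual_pattern": [r.visual_pattern for r in records],
            "ri": [r.ri for r in records],
            "woind_percent": [r.woind_percent for r in records],
            "histology": [r.histology.value for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Planar count images
# ---------------------------------------------------------------------------

_METADATA_KEYS = (
    "t_acq_min",
    "frame_duration_s",
    "tracer",
    "injected_activity_MBq",
    "magnification",
)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _load_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(
            f"no acquisition metadata: expected sidecar {sidecar.name} next to {path.name}"
        )
    return json.loads(sidecar.read_text())


def _image_from_array(arr: np.ndarray, meta: dict) -> PlanarImage:
    tracer = Tracer(meta.get("tracer", Tracer.MIBI.value))
    return PlanarImage(
        counts=arr,
        t_acq_min=float(meta["t_acq_min"]),
        frame_duration_s=float(meta["frame_duration_s"]),
        tracer=tracer,
        injected_activity_MBq=meta.get("injected_activity_MBq"),
        magnification=float(meta.get("magnification", 1.0)),
    )


def read_planar_image(path, format: Optional[str] = None) -> PlanarImage:
    """Read a planar count image (16-bit PGM/PNG, or DICOM) with its metadata.

    Raster dialects require integral non-negative pixel payloads; metadata is
    taken from the ``<name>.<ext>.meta.json`` sidecar (raster) or from the
    DICOM header where present, sidecar otherwise.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("pgm", "png"):
        with _PILImage.open(path) as img:
            arr = np.asarray(img)
        if arr.ndim != 2:
            raise FormatError(f"{path.name}: expected single-channel grayscale raster")
        if not np.issubdtype(arr.dtype, np.integer) or np.any(np.asarray(arr, np.int64) < 0):
            raise FormatError(f"{path.name}: pixel payload must be non-negative integers")
        meta = _load_sidecar(path)
        return _image_from_array(arr.astype(np.int64), meta)
    if fmt in ("dcm", "dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = np.asarray(ds.pixel_array)
        if arr.ndim != 2:
            raise FormatError(f"{path.name}: expected a single planar frame")
        if not np.issubdtype(arr.dtype, np.integer) or np.any(arr < 0):
            raise FormatError(f"{path.name}: pixel payload must be non-negative integers")
        if _sidecar_path(path).exists():
            meta = _load_sidecar(path)
        elif "ActualFrameDuration" in ds and "ImageComments" in ds:
            # Secondary-capture convention used by write: frame duration in ms,
            # minutes post-injection stashed in ImageComments.
            meta = {
                "t_acq_min": float(ds.ImageComments),
                "frame_duration_s": float(ds.ActualFrameDuration) / 1000.0,
            }
        else:
            raise FormatError(
                f"{path.name}: DICOM header lacks acquisition metadata and no "
                f"sidecar {_sidecar_path(path).name} exists"
            )
        return _image_from_array(arr.astype(np.int64), meta)
    raise FormatError(f"unsupported image format {fmt!r} for {path.name}")


def write_planar_image(image: PlanarImage, path, format: Optional[str] = None) -> Path:
    """Write a planar image as 16-bit PGM/PNG plus a JSON metadata sidecar.

    The raster dialects store integer counts; non-integral rasters (noiseless
    synthetic or decay-corrected data) are rejected rather than silently
    rounded.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("pgm", "png", "dcm", "dicom"):
        raise FormatError(f"unsupported output format {fmt!r}")
    if not image.is_integral():
        raise FormatError(
            "raster dialects store integer counts; this image is real-valued"
        )
    arr = np.asarray(image.counts)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise FormatError("counts exceed the 16-bit raster range")
    if fmt in ("dcm", "dicom"):
        _write_dicom(image, arr.astype(np.uint16), path)
        return path
    pil = _PILImage.fromarray(arr.astype(np.uint16))
    if fmt == "pgm":
        pil.save(path, format="PPM")
    else:
        pil.save(path, format="PNG")
    meta = {
        "t_acq_min": image.t_acq_min,
        "frame_duration_s": image.frame_duration_s,
        "tracer": image.tracer.value,
        "injected_activity_MBq": image.injected_activity_MBq,
        "magnification": image.magnification,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _write_dicom(image: PlanarImage, arr: np.ndarray, path: Path) -> None:
    """Minimal secondary-capture DICOM with the acquisition metadata inline."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    ds.ActualFrameDuration = int(round(image.frame_duration_s * 1000))
    ds.ImageComments = repr(image.t_acq_min)
    pydicom.dcmwrite(path, ds, enforce_file_format=True)


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------


def _pixels_in_polygon(vertices: Sequence[Sequence[float]], grid: tuple[int, int]):
    """Pixel centres inside a polygon, top/left boundary inclusive.

    Membership is evaluated at the pixel centre nudged by +1e-9 in x and y,
    which makes left/top edges inclusive and right/bottom edges exclusive for
    axis-aligned boundaries (a documented, deterministic tie-break).
    """
    from shapely.geometry import Point, Polygon

    rows, cols = grid
    poly = Polygon([(float(x), float(y)) for x, y in vertices])
    if not poly.is_valid or poly.area == 0:
        raise FormatError("polygon is degenerate or self-intersecting")
    minx, miny, maxx, maxy = poly.bounds
    if minx < -0.5 or miny < -0.5 or maxx > cols - 0.5 or maxy > rows - 0.5:
        raise FormatError("polygon vertex outside the image grid")
    eps = 1e-9
    pixels = set()
    for r in range(max(0, int(np.floor(miny))), min(rows, int(np.ceil(maxy)) + 1)):
        for c in range(max(0, int(np.floor(minx))), min(cols, int(np.ceil(maxx)) + 1)):
            if poly.contains(Point(c + eps, r + eps)):
                pixels.add((r, c))
    return pixels


def read_roi_mask(
    path, grid: tuple[int, int], label: Optional[RoiLabel] = None
) -> RoiMask:
    """Read an ROI from an 8-bit mask raster (nonzero = member) or JSON polygon.

    For rasters the file shape must equal ``grid``; ``label`` must be given.
    For polygons the JSON object is ``{"label": ..., "vertices": [[x, y], ...]}``
    and ``label`` defaults to the stored one.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        stored = payload.get("label")
        roi_label = label or (RoiLabel(stored) if stored else None)
        if roi_label is None:
            raise FormatError(f"{path.name}: polygon carries no label and none given")
        pixels = _pixels_in_polygon(payload["vertices"], grid)
        if not pixels:
            raise FormatError(f"{path.name}: polygon encloses no pixel centres")
        return RoiMask(pixels=frozenset(pixels), label=roi_label, source_grid=grid)
    if label is None:
        raise FormatError(f"{path.name}: raster masks need an explicit label")
    with _PILImage.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: mask raster must be single-channel")
    if tuple(arr.shape) != tuple(grid):
        raise FormatError(
            f"{path.name}: mask shape {arr.shape} does not match grid {grid}"
        )
    if not np.any(arr):
        raise FormatError(f"{path.name}: mask is empty")
    return RoiMask.from_mask_array(arr, label)


def write_roi_mask(roi: RoiMask, path) -> Path:
    """Write an ROI as an 8-bit mask raster (PGM or PNG, by extension)."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("pgm", "png"):
        raise FormatError(f"unsupported mask format {fmt!r}")
    arr = (roi.to_mask_array() * 255).astype(np.uint8)
    pil = _PILImage.fromarray(arr)
    pil.save(path, format="PPM" if fmt == "pgm" else "PNG")
    return path
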