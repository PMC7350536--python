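"""DICOM CT / RT-STRUCT ingestion and polygon-to-mask rasterization.

This module owns the geometry conventions the rest of the package relies on:

* masks are indexed ``(row, col)``, 0-based, aligned to the CT pixel grid;
* the patient-to-pixel mapping uses ``ImagePositionPatient`` and
  ``PixelSpacing`` (axial slices, identity orientation);
* a pixel belongs to a contour when its *center* is inside the polygon set
  under the even-odd parity rule, so nested contours (e.g., a lung ring)
  produce holes and multiple polygons on one slice combine by parity.

It also defines a small portable per-case archive (numpy ``.npz`` + JSON
sidecar) so the rest of the pipeline never requires DICOM round trips.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .organs import ORGANS, match_roi_name

CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"

SET_ASSIGNMENTS = ("gold", "candidate", "validation", "test")


class LoadError(RuntimeError):
    """Raised when a DICOM series or structure set cannot be ingested."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageSlice:
    """One axial CT slice with its geometry.

    ``pixel_grid`` holds intensities in HU; ``origin_mm`` is the patient
    (x, y) position of pixel (0, 0)'s center (``ImagePositionPatient``).
    """

    pixel_grid: np.ndarray
    pixel_spacing_mm: tuple[float, float]  # (row, col)
    slice_thickness_mm: float
    z_position_mm: float
    case_id: str
    slice_index: int
    origin_mm: tuple[float, float] = (0.0, 0.0)
    sop_instance_uid: str = ""
    frame_of_reference_uid: str = ""

    def __post_init__(self) -> None:
        self.pixel_grid = np.asarray(self.pixel_grid)
        if self.pixel_grid.ndim != 2 or min(self.pixel_grid.shape) < 1:
            raise ValueError("pixel_grid must be a non-empty 2D array")
        if min(self.pixel_spacing_mm) <= 0:
            raise ValueError("pixel_spacing_mm components must be positive")

    @property
    def rows(self) -> int:
        return self.pixel_grid.shape[0]

    @property
    def cols(self) -> int:
        return self.pixel_grid.shape[1]


@dataclass
class ContourPolygon:
    """A closed planar contour in patient coordinates (x, y in mm)."""

    organ: str
    vertices: np.ndarray  # (n, 2) of (x_mm, y_mm)
    z_position_mm: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y) mm")
        if len(self.vertices) < 3:
            raise ValueError("a contour polygon needs at least 3 vertices")

    def area_mm2(self) -> float:
        """Shoelace area (absolute value)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class StructureSet:
    """All contours of one case, grouped by organ."""

    case_id: str
    contours: dict[str, list[ContourPolygon]] = field(default_factory=dict)
    unmapped_rois: list[str] = field(default_factory=list)

    def add(self, polygon: ContourPolygon) -> None:
        self.contours.setdefault(polygon.organ, []).append(polygon)

    def organs(self) -> list[str]:
        return [o for o in ORGANS if self.contours.get(o)] + sorted(
            set(self.contours) - set(ORGANS)
        )

    def polygons_on(
        self, organ: str, z_mm: float, tol_mm: float = 1e-3
    ) -> list[ContourPolygon]:
        return [
            p
            for p in self.contours.get(organ, [])
            if abs(p.z_position_mm - z_mm) <= tol_mm
        ]


@dataclass
class BinaryMask:
    """A per-slice, per-organ boolean pixel grid with physical spacing."""

    grid: np.ndarray
    organ: str
    pixel_spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2D")

    @property
    def empty(self) -> bool:
        return not bool(self.grid.any())

    def area_pixels(self) -> int:
        return int(self.grid.sum())


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _crossing_parity(
    px: np.ndarray, py: np.ndarray, vertices: np.ndarray
) -> np.ndarray:
    """Even-odd crossing parity of points against one closed polygon.

    Standard half-open scanline rule: an edge (v1, v2) crosses the horizontal
    ray from point (px, py) when ``(y1 > py) != (y2 > py)`` and the
    intersection abscissa lies strictly right of px.  The half-open test makes
    shared vertices and horizontal edges unambiguous.
    """
    inside = np.zeros(px.shape, dtype=bool)
    v1 = vertices
    v2 = np.roll(vertices, -1, axis=0)
    for (x1, y1), (x2, y2) in zip(v1, v2):
        cond = (y1 > py) != (y2 > py)
        if not cond.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (px < x_int)
    return inside


def rasterize(
    polygons: Sequence[ContourPolygon], image_slice: ImageSlice, organ: str | None = None
) -> BinaryMask:
    """Rasterize closed polygons onto a slice's pixel grid.

    Pixel-center-inside test with even-odd parity; several polygons on the
    same slice combine by parity, so nested contours carve holes.  Degenerate
    polygons (zero area) are skipped with a warning.
    """
    if organ is None:
        organ = polygons[0].organ if polygons else "unknown"
    sy, sx = image_slice.pixel_spacing_mm
    x0, y0 = image_slice.origin_mm
    cols = x0 + sx * np.arange(image_slice.cols)
    rows = y0 + sy * np.arange(image_slice.rows)
    px, py = np.meshgrid(cols, rows)
    grid = np.zeros((image_slice.rows, image_slice.cols), dtype=bool)
    for poly in polygons:
        if poly.area_mm2() <= 0.0:
            warnings.warn(
                f"skipping degenerate polygon for {poly.organ} at z="
                f"{poly.z_position_mm:g} mm",
                stacklevel=2,
            )
            continue
        grid ^= _crossing_parity(px, py, poly.vertices)
    return BinaryMask(grid=grid, organ=organ, pixel_spacing_mm=(sy, sx))


def rasterize_structure_set(
    structures: StructureSet,
    series: Sequence[ImageSlice],
    organs: Iterable[str] = ORGANS,
    tol_mm: float | None = None,
) -> dict[str, list[BinaryMask]]:
    """Rasterize every organ of a structure set onto every slice of a series."""
    masks: dict[str, list[BinaryMask]] = {}
    for organ in organs:
        per_slice = []
        for sl in series:
            tol = tol_mm if tol_mm is not None else sl.slice_thickness_mm / 2
            polys = structures.polygons_on(organ, sl.z_position_mm, tol)
            per_slice.append(rasterize(polys, sl, organ=organ))
        masks[organ] = per_slice
    return masks


# ---------------------------------------------------------------------------
# DICOM CT series
# ---------------------------------------------------------------------------


def read_ct_series(directory: str | Path) -> list[ImageSlice]:
    """Read one CT series from a directory, sorted by ascending z.

    Raises :class:`LoadError` on an empty directory, mixed series, or in-plane
    pixel spacing that varies between slices.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.glob("*.dcm"))
    datasets = []
    for path in files:
        ds = pydicom.dcmread(path)
        if getattr(ds, "Modality", None) == "CT":
            datasets.append(ds)
    if not datasets:
        raise LoadError(f"no CT slices found in {directory}")
    series_uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(series_uids) > 1:
        raise LoadError(
            f"directory {directory} mixes {len(series_uids)} CT series "
            f"(SeriesInstanceUID values: {sorted(series_uids)})"
        )
    spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) > 1:
        raise LoadError(
            "non-uniform in-plane spacing across slices "
            f"(PixelSpacing tag (0028,0030) values: {sorted(spacings)})"
        )
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    case_id = str(getattr(datasets[0], "PatientID", directory.name))
    slices = []
    for idx, ds in enumerate(datasets):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float32) * slope + intercept
        spacing = tuple(float(v) for v in ds.PixelSpacing)  # (row, col)
        ipp = [float(v) for v in ds.ImagePositionPatient]
        slices.append(
            ImageSlice(
                pixel_grid=hu,
                pixel_spacing_mm=(spacing[0], spacing[1]),
                slice_thickness_mm=float(getattr(ds, "SliceThickness", 0.0)),
                z_position_mm=ipp[2],
                case_id=case_id,
                slice_index=idx,
                origin_mm=(ipp[0], ipp[1]),
                sop_instance_uid=str(ds.SOPInstanceUID),
                frame_of_reference_uid=str(getattr(ds, "FrameOfReferenceUID", "")),
            )
        )
    return slices


def write_ct_series(
    series: Sequence[ImageSlice],
    directory: str | Path,
    frame_of_reference_uid: str | None = None,
) -> str:
    """Write slices as an uncompressed DICOM CT series; returns the frame UID."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for_uid = frame_of_reference_uid or generate_uid()
    series_uid = generate_uid()
    study_uid = generate_uid()
    for sl in series:
        sop_uid = sl.sop_instance_uid or generate_uid()
        sl.sop_instance_uid = sop_uid
        sl.frame_of_reference_uid = for_uid
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CT_SOP_CLASS
        meta.MediaStorageSOPInstanceUID = sop_uid
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CT_SOP_CLASS
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.PatientID = sl.case_id
        ds.PatientName = sl.case_id
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = for_uid
        ds.InstanceNumber = sl.slice_index + 1
        ds.ImagePositionPatient = [sl.origin_mm[0], sl.origin_mm[1], sl.z_position_mm]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [sl.pixel_spacing_mm[0], sl.pixel_spacing_mm[1]]
        ds.SliceThickness = sl.slice_thickness_mm
        ds.Rows, ds.Columns = sl.rows, sl.cols
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed, HU can be negative
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.round(sl.pixel_grid).astype(np.int16).tobytes()
        ds.save_as(directory / f"ct_{sl.slice_index:04d}.dcm", enforce_file_format=True)
    return for_uid


# ---------------------------------------------------------------------------
# DICOM RT-STRUCT
# ---------------------------------------------------------------------------


def read_rtstruct(
    file: str | Path,
    series: Sequence[ImageSlice],
    aliases: Mapping[str, Iterable[str]] | None = None,
    z_tolerance_mm: float | None = None,
) -> StructureSet:
    """Read an RT-STRUCT and map its ROIs to the canonical organ labels.

    Contours are attached to the nearest slice z within tolerance (default:
    half the slice thickness); unmapped ROI names are collected on the result
    rather than being fatal.  A frame-of-reference mismatch with the series
    is an error.
    """
    ds = pydicom.dcmread(file)
    case_id = str(getattr(ds, "PatientID", series[0].case_id if series else ""))
    series_for = _series_frame_of_reference(ds)
    ct_for = _ct_frame_of_reference(series)
    if series_for and ct_for and series_for != ct_for:
        raise LoadError(
            f"RT-STRUCT frame of reference {series_for} does not match "
            f"the CT series frame of reference {ct_for}"
        )
    roi_names = {
        int(item.ROINumber): str(item.ROIName)
        for item in getattr(ds, "StructureSetROISequence", [])
    }
    result = StructureSet(case_id=case_id)
    z_values = np.array([sl.z_position_mm for sl in series]) if series else None
    thickness = series[0].slice_thickness_mm if series else 0.0
    tol = z_tolerance_mm if z_tolerance_mm is not None else thickness / 2
    for roi in getattr(ds, "ROIContourSequence", []):
        name = roi_names.get(int(roi.ReferencedROINumber), "")
        organ = match_roi_name(name, aliases)
        if organ is None:
            result.unmapped_rois.append(name)
            continue
        for contour in getattr(roi, "ContourSequence", []):
            data = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            z = float(np.median(data[:, 2]))
            if z_values is not None and len(z_values):
                nearest = float(z_values[np.argmin(np.abs(z_values - z))])
                if abs(nearest - z) > max(tol, 1e-6):
                    raise LoadError(
                        f"contour for ROI '{name}' at z={z:g} mm matches no "
                        f"slice within {tol:g} mm"
                    )
                z = nearest
            result.add(ContourPolygon(organ=organ, vertices=data[:, :2], z_position_mm=z))
    if not result.contours:
        warnings.warn(
            f"no mappable ROI in {file} (found: {result.unmapped_rois})",
            stacklevel=2,
        )
    return result


def _series_frame_of_reference(ds: Dataset) -> str | None:
    for item in getattr(ds, "ReferencedFrameOfReferenceSequence", []):
        return str(item.FrameOfReferenceUID)
    return None


def _ct_frame_of_reference(series: Sequence[ImageSlice]) -> str | None:
    if series and series[0].frame_of_reference_uid:
        return series[0].frame_of_reference_uid
    return None


def write_rtstruct(
    structures: StructureSet,
    series: Sequence[ImageSlice],
    file: str | Path,
    frame_of_reference_uid: str | None = None,
) -> None:
    """Write a structure set as a minimal DICOM RT-STRUCT referencing a series."""
    for_uid = frame_of_reference_uid or generate_uid()
    sop_uid = generate_uid()
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTSTRUCT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.PatientID = structures.case_id
    ds.PatientName = structures.case_id
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.StructureSetLabel = "contourqa"

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = for_uid
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    z_to_sop = {round(sl.z_position_mm, 4): sl.sop_instance_uid for sl in series}
    roi_seq, contour_seq = [], []
    for number, organ in enumerate(structures.organs(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = organ
        roi.ReferencedFrameOfReferenceUID = for_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)
        roi_contour = Dataset()
        roi_contour.ReferencedROINumber = number
        items = []
        for poly in structures.contours.get(organ, []):
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = len(poly.vertices)
            xyz = np.column_stack(
                [poly.vertices, np.full(len(poly.vertices), poly.z_position_mm)]
            )
            item.ContourData = [float(v) for v in xyz.ravel()]
            sop = z_to_sop.get(round(poly.z_position_mm, 4))
            if sop:
                ref = Dataset()
                ref.ReferencedSOPClassUID = CT_SOP_CLASS
                ref.ReferencedSOPInstanceUID = sop
                item.ContourImageSequence = [ref]
            items.append(item)
        roi_contour.ContourSequence = items
        contour_seq.append(roi_contour)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(file, enforce_file_format=True)


# ---------------------------------------------------------------------------
# Dataset layout
# ---------------------------------------------------------------------------


def dataset_manifest(root: str | Path, strict: bool = False) -> pd.DataFrame:
    """Tabulate the cases under ``root`` with their set assignment.

    ``root`` holds one directory per case plus ``manifest.csv`` with columns
    ``case_id`` and ``set_assignment``.  Assignments are always read from the
    manifest, never inferred.  Rows are sorted by case_id; a case directory
    without any CT data yields an error row (or an exception in strict mode).
    """
    root = Path(root)
    manifest_file = root / "manifest.csv"
    if not manifest_file.exists():
        raise LoadError(f"missing manifest file {manifest_file}")
    manifest = pd.read_csv(manifest_file, dtype=str)
    if manifest["case_id"].duplicated().any():
        dupes = manifest.loc[manifest["case_id"].duplicated(), "case_id"].tolist()
        raise LoadError(f"duplicate case_id in manifest: {dupes}")
    bad = set(manifest["set_assignment"]) - set(SET_ASSIGNMENTS)
    if bad:
        raise LoadError(f"unknown set assignments {sorted(bad)}")
    rows = []
    for _, entry in manifest.sort_values("case_id").iterrows():
        case_dir = root / entry.case_id
        has_ct = case_dir.is_dir() and (
            any(case_dir.glob("*.dcm")) or (case_dir / "case.npz").exists()
        )
        organs_present: list[str] = []
        error = ""
        if not has_ct:
            error = "no CT data"
            if strict:
                raise LoadError(f"case {entry.case_id}: no CT data in {case_dir}")
        elif (case_dir / "case.json").exists():
            meta = json.loads((case_dir / "case.json").read_text())
            organs_present = meta.get("organs", [])
        rows.append(
            {
                "case_id": entry.case_id,
                "set_assignment": entry.set_assignment,
                "organs": ",".join(organs_present),
                "error": error,
            }
        )
    return pd.DataFrame(rows, columns=["case_id", "set_assignment", "organs", "error"])


# ---------------------------------------------------------------------------
# Internal portable archive (no DICOM needed)
# ---------------------------------------------------------------------------


def save_case_archive(
    directory: str | Path,
    series: Sequence[ImageSlice],
    masks: Mapping[str, Sequence[BinaryMask]],
) -> None:
    """Persist a case as ``case.npz`` (images + masks) with a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    organs = [o for o in masks]
    arrays = {
        "images": np.stack([sl.pixel_grid for sl in series]).astype(np.float32),
        "z": np.array([sl.z_position_mm for sl in series]),
    }
    for organ in organs:
        arrays[f"mask_{organ}"] = np.stack([m.grid for m in masks[organ]])
    np.savez_compressed(directory / "case.npz", **arrays)
    meta = {
        "case_id": series[0].case_id,
        "organs": organs,
        "pixel_spacing_mm": list(series[0].pixel_spacing_mm),
        "slice_thickness_mm": series[0].slice_thickness_mm,
        "origin_mm": list(series[0].origin_mm),
    }
    (directory / "case.json").write_text(json.dumps(meta, indent=1))


def load_case_archive(
    directory: str | Path,
) -> tuple[list[ImageSlice], dict[str, list[BinaryMask]]]:
    """Inverse of :func:`save_case_archive`."""
    directory = Path(directory)
    meta = json.loads((directory / "case.json").read_text())
    data = np.load(directory / "case.npz")
    spacing = tuple(meta["pixel_spacing_mm"])
    series = [
        ImageSlice(
            pixel_grid=data["images"][i],
            pixel_spacing_mm=spacing,
            slice_thickness_mm=meta["slice_thickness_mm"],
            z_position_mm=float(data["z"][i]),
            case_id=meta["case_id"],
            slice_index=i,
            origin_mm=tuple(meta["origin_mm"]),
        )
        for i in range(data["images"].shape[0])
    ]
    masks = {
        organ: [
            BinaryMask(grid=data[f"mask_{organ}"][i], organ=organ, pixel_spacing_mm=spacing)
            for i in range(data[f"mask_{organ}"].shape[0])
        ]
        for organ in meta["organs"]
    }
    return series, masks
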