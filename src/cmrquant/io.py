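"""Readers and writers for short-axis image stacks, contours and measurement tables.

The pipeline touches four on-disk artefacts:

* 3-D signal-intensity stacks, as NIfTI files or DICOM series directories
  (:func:`read_stack` / :func:`write_stack`);
* per-slice endocardial/epicardial contours, as a small JSON format
  (:func:`read_contours` / :func:`write_contours`);
* long-format observer measurement tables ("ratings"), as delimited text
  (:func:`read_ratings` / :func:`write_ratings`).

Conventions, stated once and tested in round-trips: voxel arrays are indexed
``(slice, row, column)`` with slice 0 the most basal slice; contour
coordinates are 0-based, pixel-centred ``[row, column]`` pairs; signal
intensity is carried in arbitrary units and never rescaled beyond the
format-mandated slope/intercept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ImageStack",
    "SliceContours",
    "ContourSet",
    "read_stack",
    "write_stack",
    "read_contours",
    "write_contours",
    "read_ratings",
    "write_ratings",
    "validate_ratings",
    "RATINGS_COLUMNS",
]

MODALITIES = ("LGE", "T2w")
FIELD_STRENGTHS = ("1.5T", "3.0T")
MEASURES = ("IS", "AAR")

#: Canonical long-format ratings columns; one row per measurement in %LVM.
RATINGS_COLUMNS = [
    "subject",
    "field_strength",
    "measure",
    "method",
    "rater",
    "replicate",
    "value",
]


class FormatError(ValueError):
    """A file failed validation against one of the package's formats."""


@dataclass
class ImageStack:
    """A short-axis signal-intensity volume with its physical geometry.

    Parameters
    ----------
    voxels
        3-D float array indexed ``(slice, row, column)``, base to apex.
    pixel_spacing
        In-plane spacing ``(row_mm, col_mm)``.
    slice_thickness, slice_gap
        Slice thickness and inter-slice gap in mm; the centre-to-centre
        slice spacing is their sum.
    modality
        ``"LGE"`` (infarct imaging) or ``"T2w"`` (oedema imaging).
    quality_grade
        Optional image-quality grade, 0 (unanalysable) to 3 (excellent);
        carried as metadata only.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    slice_gap: float = 0.0
    modality: str = "LGE"
    quality_grade: int | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise FormatError("voxels must be a 3-D (slice, row, col) array")
        if self.voxels.shape[0] < 2:
            raise FormatError("an ImageStack needs >= 2 slices")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if min(self.pixel_spacing) <= 0:
            raise FormatError("pixel spacing must be positive")
        if self.slice_thickness <= 0:
            raise FormatError("slice thickness must be positive")
        if self.slice_gap < 0:
            raise FormatError("slice gap must be >= 0")
        if self.modality not in MODALITIES:
            raise FormatError(f"modality must be one of {MODALITIES}")
        if self.quality_grade is not None and self.quality_grade not in (0, 1, 2, 3):
            raise FormatError("quality_grade must be in {0,1,2,3}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_spacing(self) -> float:
        """Centre-to-centre slice spacing (thickness + gap), mm."""
        return self.slice_thickness + self.slice_gap

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_area_mm2 * self.slice_spacing


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as NIfTI; geometry round-trips through the header."""
    import nibabel as nib

    path = Path(path)
    # NIfTI x,y,z = col,row,slice
    data = np.transpose(stack.voxels, (2, 1, 0))
    affine = np.diag(
        [stack.pixel_spacing[1], stack.pixel_spacing[0], stack.slice_spacing, 1.0]
    )
    img = nib.Nifti1Image(data, affine)
    img.header.set_data_dtype(np.float64)
    img.header.set_zooms(
        (stack.pixel_spacing[1], stack.pixel_spacing[0], stack.slice_spacing)
    )
    q = -1 if stack.quality_grade is None else stack.quality_grade
    img.header["descrip"] = (
        f"thk={stack.slice_thickness:g};gap={stack.slice_gap:g};"
        f"mod={stack.modality};q={q}".encode()
    )
    nib.save(img, str(path))
    return path


def _parse_descrip(raw: bytes | str) -> dict[str, str]:
    text = raw.decode() if isinstance(raw, bytes) else str(raw)
    out: dict[str, str] = {}
    for chunk in text.split(";"):
        if "=" in chunk:
            key, val = chunk.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def _read_nifti(path: Path) -> ImageStack:
    import nibabel as nib

    img = nib.load(str(path))
    zooms = [float(z) for z in img.header.get_zooms()[:3]]
    if min(zooms) <= 0:
        raise FormatError(f"{path}: non-positive voxel spacing in header")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    voxels = np.transpose(data, (2, 1, 0)).astype(float)
    meta = _parse_descrip(img.header["descrip"].item())
    thickness = float(meta["thk"]) if "thk" in meta else zooms[2]
    gap = float(meta["gap"]) if "gap" in meta else 0.0
    modality = meta.get("mod", "LGE")
    quality = int(meta["q"]) if "q" in meta else -1
    return ImageStack(
        voxels=voxels,
        pixel_spacing=(zooms[1], zooms[0]),
        slice_thickness=thickness,
        slice_gap=gap,
        modality=modality if modality in MODALITIES else "LGE",
        quality_grade=None if quality < 0 else quality,
    )


def _read_dicom_series(dirpath: Path, modality: str = "LGE") -> ImageStack:
    import pydicom

    files = sorted(p for p in dirpath.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if len(datasets) < 2:
        raise FormatError(f"{dirpath}: fewer than 2 DICOM image slices found")

    ref = datasets[0]
    if not hasattr(ref, "PixelSpacing"):
        raise FormatError(f"{dirpath}: PixelSpacing missing; refusing to guess")
    spacing = [float(v) for v in ref.PixelSpacing]
    orient = np.array([float(v) for v in ref.ImageOrientationPatient])
    for ds in datasets[1:]:
        if not np.allclose(
            [float(v) for v in ds.ImageOrientationPatient], orient, atol=1e-6
        ):
            raise FormatError(f"{dirpath}: inconsistent slice orientation in series")
        if not np.allclose([float(v) for v in ds.PixelSpacing], spacing, atol=1e-6):
            raise FormatError(f"{dirpath}: inconsistent pixel spacing in series")

    row_dir, col_dir = orient[:3], orient[3:]
    normal = np.cross(row_dir, col_dir)
    positions = [
        float(np.dot([float(v) for v in ds.ImagePositionPatient], normal))
        for ds in datasets
    ]
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    def _pixels(ds) -> np.ndarray:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept

    voxels = np.stack([_pixels(ds) for ds in datasets], axis=0)
    steps = np.diff(positions)
    slice_spacing = float(np.median(np.abs(steps))) if len(steps) else 0.0
    thickness = float(getattr(ref, "SliceThickness", slice_spacing))
    if thickness <= 0:
        raise FormatError(f"{dirpath}: slice thickness missing; refusing to guess")
    gap = max(slice_spacing - thickness, 0.0)
    return ImageStack(
        voxels=voxels,
        pixel_spacing=(spacing[0], spacing[1]),
        slice_thickness=thickness,
        slice_gap=gap,
        modality=modality,
    )


def read_stack(path: str | Path, format: str | None = None, modality: str = "LGE") -> ImageStack:
    """Read an :class:`ImageStack` from NIfTI or a DICOM series directory.

    ``format`` may be ``"nifti"`` or ``"dicom"``; by default a directory is
    read as a DICOM series and a file as NIfTI.
    """
    path = Path(path)
    if format is None:
        format = "dicom" if path.is_dir() else "nifti"
    format = format.lower()
    if format == "nifti":
        return _read_nifti(path)
    if format in ("dicom", "dicom-series"):
        return _read_dicom_series(path, modality=modality)
    raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# contours


@dataclass
class SliceContours:
    """Endo- and epicardial polygons on one slice, pixel-centred [row, col]."""

    endo: np.ndarray
    epi: np.ndarray

    def __post_init__(self) -> None:
        for name in ("endo", "epi"):
            poly = np.asarray(getattr(self, name), dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise FormatError(f"{name} contour must be an (n>=3, 2) vertex array")
            # drop an explicit closing vertex; polygons are implicitly closed
            if np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]
            setattr(self, name, poly)


@dataclass
class ContourSet:
    """Per-slice contour pairs keyed by slice index (0 = most basal)."""

    slices: dict[int, SliceContours] = field(default_factory=dict)

    def slice_indices(self) -> list[int]:
        return sorted(self.slices)

    def __len__(self) -> int:
        return len(self.slices)


def _check_simple(poly: np.ndarray, label: str) -> None:
    from shapely.geometry import Polygon

    if not Polygon(poly[:, ::-1]).is_valid:
        warnings.warn(
            f"{label}: polygon is self-intersecting; keeping it as drawn",
            stacklevel=3,
        )


def write_contours(contours: ContourSet, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "convention": "0-based pixel-centred [row, col]; slice 0 most basal; "
        "polygons implicitly closed",
        "slices": [
            {
                "slice": int(s),
                "endo": np.asarray(sc.endo, float).tolist(),
                "epi": np.asarray(sc.epi, float).tolist(),
            }
            for s, sc in sorted(contours.slices.items())
        ],
    }
    path.write_text(json.dumps(payload))
    return path


def read_contours(path: str | Path) -> ContourSet:
    """Read the JSON contour format; both contours required wherever one is."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    if "slices" not in payload or not isinstance(payload["slices"], list):
        raise FormatError(f"{path}: missing 'slices' list")
    out: dict[int, SliceContours] = {}
    for entry in payload["slices"]:
        if "slice" not in entry:
            raise FormatError(f"{path}: slice entry without index")
        idx = int(entry["slice"])
        if ("endo" in entry) != ("epi" in entry):
            raise FormatError(
                f"{path}: slice {idx} has only one contour; myocardium undefined"
            )
        sc = SliceContours(
            endo=np.asarray(entry["endo"], float), epi=np.asarray(entry["epi"], float)
        )
        _check_simple(sc.endo, f"{path} slice {idx} endo")
        _check_simple(sc.epi, f"{path} slice {idx} epi")
        if idx in out:
            raise FormatError(f"{path}: duplicate slice index {idx}")
        out[idx] = sc
    return ContourSet(slices=out)


# ---------------------------------------------------------------------------
# ratings tables


def validate_ratings(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the RatingsTable contract on a long-format DataFrame."""
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ratings table missing columns: {missing}")
    df = df[RATINGS_COLUMNS].copy()
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna()].tolist()
    if bad:
        raise FormatError(f"non-numeric 'value' in rows {bad}")
    df["value"] = values.astype(float)
    if (df["value"] < 0).any() or (df["value"] > 100).any():
        raise FormatError("ratings values must lie in [0, 100] %LVM")
    if not df["field_strength"].isin(FIELD_STRENGTHS).all():
        raise FormatError(f"field_strength must be one of {FIELD_STRENGTHS}")
    if not df["measure"].isin(MEASURES).all():
        raise FormatError(f"measure must be one of {MEASURES}")
    key = ["subject", "field_strength", "measure", "method", "rater", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise FormatError(
            f"duplicate (subject, measure, method, rater, replicate) keys in rows "
            f"{df.index[dup].tolist()}"
        )
    return df


def read_ratings(
    path: str | Path, column_map: dict[str, str] | None = None, sep: str = ","
) -> pd.DataFrame:
    """Load a long-format ratings table.

    ``column_map`` maps file column names to the canonical names in
    :data:`RATINGS_COLUMNS`, so externally produced tables can be ingested
    without code changes.
    """
    df = pd.read_csv(Path(path), sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    try:
        return validate_ratings(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_ratings(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_ratings(df).to_csv(path, index=False)
    return path
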