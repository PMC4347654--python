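"""Myocardial geometry: contour rasterisation, ROIs, LV mass, slice rules.

A voxel belongs to the myocardium iff its centre lies strictly inside the
epicardial polygon and not inside the endocardial polygon. The most apical
contoured slice is excluded from quantification by default to minimise
partial-volume effect; by the package's convention the excluded slice
contributes to neither the numerator nor the denominator of %LVM (an
``include_excluded`` switch covers the other convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io import ContourSet, ImageStack

__all__ = [
    "GeometryError",
    "MyoMask",
    "Roi",
    "rasterize",
    "lv_mass",
    "mass_of",
    "build_roi",
    "exclude_apical_slice",
    "DEFAULT_DENSITY_G_PER_ML",
    "DEFAULT_ROI_AREA_CM2",
]

#: Myocardial tissue density. %LVM results are density-invariant (the factor
#: cancels in the enhanced-mass / LV-mass ratio); absolute masses are not.
DEFAULT_DENSITY_G_PER_ML = 1.05

#: Remote / infarct-core ROI area used by the kSD and FWHM methods.
DEFAULT_ROI_AREA_CM2 = 2.0


class GeometryError(ValueError):
    """Invalid geometry (contours, masks or ROI requests)."""


@dataclass
class MyoMask:
    """Boolean myocardial volume plus per-slice bookkeeping flags."""

    mask: np.ndarray  # bool, (slice, row, col)
    contoured: np.ndarray  # bool per slice
    excluded_apical: np.ndarray  # bool per slice

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        self.contoured = np.asarray(self.contoured, bool)
        self.excluded_apical = np.asarray(self.excluded_apical, bool)
        if self.mask.ndim != 3:
            raise GeometryError("mask must be 3-D (slice, row, col)")
        n = self.mask.shape[0]
        if self.contoured.shape != (n,) or self.excluded_apical.shape != (n,):
            raise GeometryError("per-slice flags must have one entry per slice")

    @property
    def quantifiable(self) -> np.ndarray:
        """Slices that contribute to quantification (contoured, not excluded)."""
        return self.contoured & ~self.excluded_apical

    def quantifiable_volume(self) -> np.ndarray:
        """Myocardial voxels on quantifiable slices."""
        return self.mask & self.quantifiable[:, None, None]

    def contoured_volume(self) -> np.ndarray:
        return self.mask & self.contoured[:, None, None]


@dataclass
class Roi:
    """A fixed-area region of interest within the myocardium of one slice."""

    slice_index: int
    rows: np.ndarray
    cols: np.ndarray
    target_area_cm2: float
    kind: str = "remote"  # or "infarct-core"

    @property
    def n_voxels(self) -> int:
        return len(self.rows)


def rasterize(contours: ContourSet, stack: ImageStack) -> MyoMask:
    """Rasterise endo/epi contour pairs into a myocardial mask.

    Deterministic: a voxel is myocardium iff its centre is strictly inside
    the epicardial polygon and not strictly inside the endocardial polygon.
    Degenerate endo == epi yields an empty slice with a warning; an
    endocardial contour not contained in its epicardial contour is an error.
    """
    import shapely
    from shapely.geometry import Polygon

    n_slices, n_rows, n_cols = stack.voxels.shape
    mask = np.zeros((n_slices, n_rows, n_cols), bool)
    contoured = np.zeros(n_slices, bool)
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    xs = cc.ravel().astype(float)
    ys = rr.ravel().astype(float)

    for idx, sc in contours.slices.items():
        if idx < 0 or idx >= n_slices:
            raise GeometryError(f"contoured slice {idx} outside stack of {n_slices}")
        endo_poly = Polygon(sc.endo[:, ::-1])  # (x=col, y=row)
        epi_poly = Polygon(sc.epi[:, ::-1])
        contoured[idx] = True
        if endo_poly.equals(epi_poly):
            warnings.warn(
                f"slice {idx}: endo == epi; myocardium empty on this slice",
                stacklevel=2,
            )
            continue
        if not epi_poly.covers(endo_poly):
            raise GeometryError(f"slice {idx}: endocardial contour not inside epicardial")
        inside_epi = shapely.contains_xy(epi_poly, xs, ys)
        inside_endo = shapely.contains_xy(endo_poly, xs, ys)
        mask[idx] = (inside_epi & ~inside_endo).reshape(n_rows, n_cols)

    return MyoMask(mask=mask, contoured=contoured, excluded_apical=np.zeros(n_slices, bool))


def mass_of(
    volume: np.ndarray, stack: ImageStack, density: float = DEFAULT_DENSITY_G_PER_ML
) -> float:
    """Mass in grams of an arbitrary boolean voxel volume."""
    count = int(np.asarray(volume, bool).sum())
    return count * stack.voxel_volume_mm3 / 1000.0 * density


def lv_mass(
    myo: MyoMask,
    stack: ImageStack,
    density: float = DEFAULT_DENSITY_G_PER_ML,
    include_excluded: bool = False,
) -> float:
    """LV myocardial mass (g) = voxels x pixel area x (thickness+gap) x density.

    By default only quantifiable slices count; ``include_excluded`` adds the
    excluded apical slice back into the total.
    """
    vol = myo.contoured_volume() if include_excluded else myo.quantifiable_volume()
    if not vol.any():
        raise GeometryError("empty myocardial mask; LV mass undefined")
    return mass_of(vol, stack, density)


def build_roi(
    myo: MyoMask,
    stack: ImageStack,
    slice_index: int,
    seed_point: tuple[float, float],
    target_area_cm2: float = DEFAULT_ROI_AREA_CM2,
    kind: str = "remote",
    avoid_rim_px: int = 0,
) -> Roi:
    """The N myocardial voxels nearest the seed, N = round(area / pixel area).

    The seed is snapped to the centre of its containing pixel before distance
    ranking, so the ROI is invariant to sub-pixel seed perturbation.
    Distances are Euclidean in mm; ties break deterministically by
    (row, column). Observer-style ROI variability is modelled by moving the
    seed by whole pixels.

    ``avoid_rim_px`` erodes the candidate myocardium by that many pixels
    before ranking, emulating how observers keep a reference ROI off the
    partial-volume rim at the blood-pool and epicardial borders; if the
    eroded band is too small for the target area the full myocardium is
    used. The ROI always remains a subset of the myocardium.
    """
    sl = myo.mask[slice_index]
    r0, c0 = int(round(seed_point[0])), int(round(seed_point[1]))
    if r0 < 0 or c0 < 0 or r0 >= sl.shape[0] or c0 >= sl.shape[1] or not sl[r0, c0]:
        raise GeometryError(f"seed {seed_point} is not myocardial on slice {slice_index}")
    n_target = int(round(target_area_cm2 * 100.0 / stack.pixel_area_mm2))
    candidates = sl
    if avoid_rim_px > 0:
        from scipy import ndimage

        eroded = ndimage.binary_erosion(
            sl, structure=np.ones((3, 3), bool), iterations=avoid_rim_px
        )
        if eroded.sum() >= n_target:
            candidates = eroded
    rows, cols = np.nonzero(candidates)
    if len(rows) < n_target:
        raise GeometryError(
            f"slice {slice_index}: myocardial area "
            f"{len(rows) * stack.pixel_area_mm2 / 100:.2f} cm2 "
            f"< ROI target {target_area_cm2} cm2"
        )
    d2 = ((rows - r0) * stack.pixel_spacing[0]) ** 2 + (
        (cols - c0) * stack.pixel_spacing[1]
    ) ** 2
    order = np.lexsort((cols, rows, d2))[:n_target]
    return Roi(
        slice_index=slice_index,
        rows=rows[order],
        cols=cols[order],
        target_area_cm2=target_area_cm2,
        kind=kind,
    )


def exclude_apical_slice(myo: MyoMask) -> MyoMask:
    """Flag the most apical contoured slice as excluded (idempotent)."""
    contoured_idx = np.nonzero(myo.contoured)[0]
    if len(contoured_idx) < 2:
        raise GeometryError("apical exclusion needs >= 2 contoured slices")
    apical = int(contoured_idx.max())  # slice 0 is most basal
    excluded = myo.excluded_apical.copy()
    excluded[apical] = True
    return replace(myo, excluded_apical=excluded)
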