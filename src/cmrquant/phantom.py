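"""Synthetic short-axis cardiac MR phantom with exact ground truth.

The phantom is an idealised left ventricle: on every slice the myocardium is
an annulus (endocardial and epicardial circles), the infarct is a circular
sector of that annulus with adjustable angular extent and transmurality, and
the oedematous area-at-risk is a wider, transmural sector containing the
infarct. An optional hypointense core (microvascular obstruction on LGE,
intramyocardial haemorrhage on T2w) occupies the innermost fraction of the
infarct. Partial volume is modelled as in-plane Gaussian blur of the
noiseless signal-intensity map, noise as additive Gaussian (Rician optional),
and false-enhancement speckles are small single-slice bright spots placed in
remote territory, disconnected from the infarct.

Because the geometry is analytic, every mask (myocardium, infarct, oedema,
MVO/IMH, speckles) is known exactly, and the true infarct size / area at
risk in %LVM follow by voxel counting — so every downstream thresholding
method and statistic can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import geometry
from .io import ContourSet, ImageStack, SliceContours, validate_ratings

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "sample_observer_table",
    "remote_seed",
    "core_seed",
    "write_phantom",
]


class PhantomError(ValueError):
    """The requested phantom geometry is invalid or does not fit the matrix."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Signal-intensity means are in arbitrary units and apply to the noise-free
    map before blur; `si_lge_border` is the LGE intensity of the oedema zone
    outside the infarct (defaults to `si_remote`, i.e. invisible on LGE; set
    an intermediate value to emulate the peri-infarct border zone that drives
    low-threshold overestimation).
    """

    n_slices: int = 8
    matrix_size: int = 128
    pixel_spacing: float = 1.5  # mm, isotropic in-plane
    slice_thickness: float = 8.0  # mm
    slice_gap: float = 2.0  # mm
    endo_radius: float = 20.0  # mm
    epi_radius: float = 30.0  # mm
    infarct_angular_extent: float = 90.0  # degrees
    infarct_transmurality: float = 0.8  # fraction of wall thickness, from endo
    infarct_slice_span: tuple[int, int] = (1, 7)  # half-open [start, stop)
    infarct_angle_deg: float = 0.0  # wedge centre direction
    oedema_angular_margin: float = 20.0  # degrees each side beyond the infarct
    mvo_fraction: float = 0.0  # fraction of infarct area forming the core
    si_remote: float = 100.0
    si_infarct: float = 400.0
    si_oedema: float = 250.0
    si_mvo: float = 50.0
    si_blood: float = 450.0
    si_background: float = 20.0
    si_lge_border: float | None = None
    noise_sd: float = 10.0
    noise_model: str = "gaussian"  # or "rician"
    blur_sigma_mm: float = 0.6
    speckle_count: int = 0
    seed: int = 0
    contour_vertices: int = 720

    def validate(self) -> None:
        if self.n_slices < 2:
            raise PhantomError("need >= 2 slices")
        if not 0 < self.endo_radius < self.epi_radius:
            raise PhantomError("need 0 < endo_radius < epi_radius")
        half_extent_mm = (self.matrix_size / 2 - 1) * self.pixel_spacing
        if self.epi_radius >= half_extent_mm:
            raise PhantomError(
                f"epi radius {self.epi_radius} mm does not fit a "
                f"{self.matrix_size}-pixel matrix at {self.pixel_spacing} mm"
            )
        if not 0 <= self.infarct_transmurality <= 1:
            raise PhantomError("infarct_transmurality must be in [0, 1]")
        if not 0 <= self.mvo_fraction < 1:
            raise PhantomError("mvo_fraction must be in [0, 1)")
        if not 0 < self.infarct_angular_extent <= 360:
            raise PhantomError("infarct_angular_extent must be in (0, 360]")
        s0, s1 = self.infarct_slice_span
        if not 0 <= s0 < s1 <= self.n_slices:
            raise PhantomError("infarct_slice_span out of range")
        if self.si_infarct <= self.si_remote:
            raise PhantomError("need si_infarct > si_remote (LGE contrast)")
        if self.si_oedema <= self.si_remote:
            raise PhantomError("need si_oedema > si_remote (T2w contrast)")
        if self.si_mvo >= self.si_infarct:
            raise PhantomError("need si_mvo < si_infarct")
        if self.noise_sd < 0 or self.blur_sigma_mm < 0 or self.speckle_count < 0:
            raise PhantomError("noise/blur/speckle parameters must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise PhantomError("noise_model must be 'gaussian' or 'rician'")

    @property
    def centre_px(self) -> float:
        return (self.matrix_size - 1) / 2.0


@dataclass
class GroundTruth:
    """Exact masks and derived true percentages for one phantom."""

    myo_mask: np.ndarray
    infarct_mask: np.ndarray
    oedema_mask: np.ndarray
    mvo_mask: np.ndarray
    imh_mask: np.ndarray
    speckle_mask: np.ndarray
    true_is_percent_lvm: float
    true_aar_percent_lvm: float
    true_msi: float
    excluded_apical_slice: int = field(default=-1)

    def to_myo_mask(self, exclude_apical: bool = True) -> geometry.MyoMask:
        """Ground-truth myocardium as a :class:`~cmrquant.geometry.MyoMask`."""
        n = self.myo_mask.shape[0]
        myo = geometry.MyoMask(
            mask=self.myo_mask.copy(),
            contoured=np.ones(n, bool),
            excluded_apical=np.zeros(n, bool),
        )
        return geometry.exclude_apical_slice(myo) if exclude_apical else myo


def _wedge(theta_deg: np.ndarray, centre_deg: float, extent_deg: float) -> np.ndarray:
    diff = (theta_deg - centre_deg + 180.0) % 360.0 - 180.0
    return np.abs(diff) <= extent_deg / 2.0


def _circle_contour(spec: PhantomSpec, radius_mm: float) -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, spec.contour_vertices, endpoint=False)
    r_px = radius_mm / spec.pixel_spacing
    rows = spec.centre_px + r_px * np.sin(ang)
    cols = spec.centre_px + r_px * np.cos(ang)
    return np.column_stack([rows, cols])


def _polar_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(spec.matrix_size, dtype=float)
    rows, cols = np.meshgrid(idx, idx, indexing="ij")
    y = (rows - spec.centre_px) * spec.pixel_spacing
    x = (cols - spec.centre_px) * spec.pixel_spacing
    dist = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    return dist, theta


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[ImageStack, ImageStack, ContourSet, GroundTruth]:
    """Generate paired LGE and T2w stacks, contours and exact ground truth.

    Identical specs (including seed) produce bit-identical output. True
    percentages are computed under the default quantification convention:
    the most apical slice excluded from both numerator and denominator.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.matrix_size
    dist, theta = _polar_grids(spec)

    blood2d = dist < spec.endo_radius
    myo2d = (dist >= spec.endo_radius) & (dist < spec.epi_radius)
    infarct_outer = spec.endo_radius + spec.infarct_transmurality * (
        spec.epi_radius - spec.endo_radius
    )
    infarct2d = (
        myo2d
        & _wedge(theta, spec.infarct_angle_deg, spec.infarct_angular_extent)
        & (dist < infarct_outer)
    )
    oedema2d = myo2d & _wedge(
        theta,
        spec.infarct_angle_deg,
        spec.infarct_angular_extent + 2 * spec.oedema_angular_margin,
    )

    # MVO core: innermost fraction of the infarct area (2-D EDT ordering),
    # hence enclosed by enhancement on every slice it appears on.
    mvo2d = np.zeros_like(infarct2d)
    if spec.mvo_fraction > 0 and infarct2d.any():
        edt = ndimage.distance_transform_edt(infarct2d)
        rows_i, cols_i = np.nonzero(infarct2d)
        n_core = int(round(spec.mvo_fraction * len(rows_i)))
        if n_core > 0:
            order = np.lexsort((cols_i, rows_i, -edt[rows_i, cols_i]))[:n_core]
            mvo2d[rows_i[order], cols_i[order]] = True

    s0, s1 = spec.infarct_slice_span
    shape = (spec.n_slices, n, n)
    myo = np.broadcast_to(myo2d, shape).copy()
    infarct = np.zeros(shape, bool)
    oedema = np.zeros(shape, bool)
    mvo = np.zeros(shape, bool)
    infarct[s0:s1] = infarct2d
    oedema[s0:s1] = oedema2d
    mvo[s0:s1] = mvo2d

    # speckles: small 2x2 single-slice bright spots in remote territory,
    # outside the oedema wedge (3-D disconnected from the infarct) and away
    # from the conventional remote-ROI site opposite the infarct (observers
    # place the reference ROI in artifact-free myocardium)
    speckle = np.zeros(shape, bool)
    forbidden_extent = spec.infarct_angular_extent + 2 * spec.oedema_angular_margin + 30.0
    remote_ang = (spec.infarct_angle_deg + 180.0) % 360.0
    mid_r = (spec.endo_radius + spec.epi_radius) / 2.0
    placed = 0
    attempts = 0
    while placed < spec.speckle_count and attempts < 200 * max(spec.speckle_count, 1):
        attempts += 1
        sl = int(rng.integers(0, spec.n_slices))
        ang = float(rng.uniform(0.0, 360.0))
        if _wedge(np.array([ang]), spec.infarct_angle_deg, forbidden_extent)[0]:
            continue
        if _wedge(np.array([ang]), remote_ang, 80.0)[0]:
            continue
        rad = float(rng.uniform(spec.endo_radius + 2.0, spec.epi_radius - 2.0)) if (
            spec.epi_radius - spec.endo_radius > 4.0
        ) else mid_r
        r_px = int(round(spec.centre_px + rad / spec.pixel_spacing * np.sin(np.radians(ang))))
        c_px = int(round(spec.centre_px + rad / spec.pixel_spacing * np.cos(np.radians(ang))))
        block = np.s_[sl, r_px : r_px + 2, c_px : c_px + 2]
        if not myo[block].all():
            continue
        # keep speckles disjoint and non-adjacent to each other
        nb = speckle[sl, max(r_px - 2, 0) : r_px + 4, max(c_px - 2, 0) : c_px + 4]
        if nb.any():
            continue
        speckle[block] = True
        placed += 1

    # noise-free signal-intensity maps
    si_border = spec.si_remote if spec.si_lge_border is None else spec.si_lge_border
    lge = np.full(shape, spec.si_background, float)
    lge[np.broadcast_to(blood2d, shape)] = spec.si_blood
    lge[myo] = spec.si_remote
    lge[oedema & ~infarct] = si_border
    lge[infarct] = spec.si_infarct
    lge[mvo] = spec.si_mvo
    lge[speckle] = spec.si_infarct

    t2w = np.full(shape, spec.si_background, float)
    t2w[np.broadcast_to(blood2d, shape)] = spec.si_blood
    t2w[myo] = spec.si_remote
    t2w[oedema] = spec.si_oedema  # infarct lies within the at-risk zone
    t2w[mvo] = spec.si_mvo  # IMH core
    t2w[speckle] = spec.si_oedema

    if spec.blur_sigma_mm > 0:
        sigma_px = spec.blur_sigma_mm / spec.pixel_spacing
        for vol in (lge, t2w):
            for s in range(spec.n_slices):
                vol[s] = ndimage.gaussian_filter(vol[s], sigma_px)

    if spec.noise_sd > 0:
        for vol in (lge, t2w):
            if spec.noise_model == "gaussian":
                vol += rng.normal(0.0, spec.noise_sd, size=shape)
            else:  # rician magnitude noise
                n1 = rng.normal(0.0, spec.noise_sd, size=shape)
                n2 = rng.normal(0.0, spec.noise_sd, size=shape)
                vol[:] = np.hypot(vol + n1, n2)

    lge_stack = ImageStack(
        voxels=lge,
        pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
        slice_thickness=spec.slice_thickness,
        slice_gap=spec.slice_gap,
        modality="LGE",
    )
    t2w_stack = ImageStack(
        voxels=t2w,
        pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
        slice_thickness=spec.slice_thickness,
        slice_gap=spec.slice_gap,
        modality="T2w",
    )

    contours = ContourSet(
        slices={
            s: SliceContours(
                endo=_circle_contour(spec, spec.endo_radius),
                epi=_circle_contour(spec, spec.epi_radius),
            )
            for s in range(spec.n_slices)
        }
    )

    apical = spec.n_slices - 1
    quant = np.ones(spec.n_slices, bool)
    quant[apical] = False
    q3 = quant[:, None, None]
    myo_n = int((myo & q3).sum())
    is_pct = 100.0 * int((infarct & q3).sum()) / myo_n
    aar_pct = 100.0 * int((oedema & q3).sum()) / myo_n
    msi = 100.0 * (aar_pct - is_pct) / aar_pct if aar_pct > 0 else float("nan")

    truth = GroundTruth(
        myo_mask=myo,
        infarct_mask=infarct,
        oedema_mask=oedema,
        mvo_mask=mvo,
        imh_mask=mvo.copy(),
        speckle_mask=speckle,
        true_is_percent_lvm=is_pct,
        true_aar_percent_lvm=aar_pct,
        true_msi=msi,
        excluded_apical_slice=apical,
    )
    return lge_stack, t2w_stack, contours, truth


def remote_seed(spec: PhantomSpec) -> tuple[int, float, float]:
    """A (slice, row, col) seed in remote myocardium, opposite the infarct."""
    ang = np.radians((spec.infarct_angle_deg + 180.0) % 360.0)
    mid_r = (spec.endo_radius + spec.epi_radius) / 2.0 / spec.pixel_spacing
    s0, _ = spec.infarct_slice_span
    return (
        s0,
        spec.centre_px + mid_r * np.sin(ang),
        spec.centre_px + mid_r * np.cos(ang),
    )


def core_seed(spec: PhantomSpec) -> tuple[int, float, float]:
    """A (slice, row, col) seed in the infarct core."""
    ang = np.radians(spec.infarct_angle_deg)
    outer = spec.endo_radius + spec.infarct_transmurality * (
        spec.epi_radius - spec.endo_radius
    )
    mid_r = (spec.endo_radius + outer) / 2.0 / spec.pixel_spacing
    s0, s1 = spec.infarct_slice_span
    return (
        (s0 + s1 - 1) // 2,
        spec.centre_px + mid_r * np.sin(ang),
        spec.centre_px + mid_r * np.cos(ang),
    )


def sample_observer_table(
    n_subjects: int,
    bias_per_method: dict[str, float],
    noise_sd: float,
    seed: int,
    field_strength: str = "1.5T",
    measure: str = "IS",
    rater: str = "R1",
    replicate: int = 1,
) -> pd.DataFrame:
    """Synthetic long-format measurement table: latent truth + bias + noise.

    Each subject gets one latent true value (uniform on 5-35 %LVM, a range
    typical of acute infarct burdens) and one measurement per method equal to
    latent + method bias + independent Gaussian noise. Reproducible by seed.
    """
    if n_subjects < 2:
        raise ValueError("need n_subjects >= 2")
    rng = np.random.default_rng(seed)
    latent = rng.uniform(5.0, 35.0, size=n_subjects)
    rows = []
    for method, bias in bias_per_method.items():
        noise = rng.normal(0.0, noise_sd, size=n_subjects) if noise_sd > 0 else np.zeros(n_subjects)
        for i in range(n_subjects):
            rows.append(
                {
                    "subject": f"S{i + 1:03d}",
                    "field_strength": field_strength,
                    "measure": measure,
                    "method": method,
                    "rater": rater,
                    "replicate": replicate,
                    "value": float(np.clip(latent[i] + bias + noise[i], 0.0, 100.0)),
                }
            )
    return validate_ratings(pd.DataFrame(rows))


def write_phantom(
    spec: PhantomSpec, out_dir: str | Path
) -> dict[str, Path]:
    """Generate a phantom and write all artefacts to ``out_dir``.

    Writes ``lge.nii.gz``, ``t2w.nii.gz``, ``contours.json`` and NIfTI label
    maps for the ground-truth masks; returns the paths.
    """
    import nibabel as nib

    from .io import write_contours, write_stack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lge, t2w, contours, truth = generate_phantom(spec)
    paths = {
        "lge": write_stack(lge, out / "lge.nii.gz"),
        "t2w": write_stack(t2w, out / "t2w.nii.gz"),
        "contours": write_contours(contours, out / "contours.json"),
    }
    labels = np.zeros(truth.myo_mask.shape, np.uint8)
    labels[truth.myo_mask] = 1
    labels[truth.oedema_mask] = 2
    labels[truth.infarct_mask] = 3
    labels[truth.mvo_mask] = 4
    labels[truth.speckle_mask] = 5
    affine = np.diag([spec.pixel_spacing, spec.pixel_spacing,
                      spec.slice_thickness + spec.slice_gap, 1.0])
    img = nib.Nifti1Image(np.transpose(labels, (2, 1, 0)), affine)
    nib.save(img, str(out / "truth_labels.nii.gz"))
    paths["truth_labels"] = out / "truth_labels.nii.gz"
    return paths
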