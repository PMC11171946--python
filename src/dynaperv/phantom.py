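"""Digital three-phase CT phantoms and the three-ROI density measurement.

A phantom is a small trio of co-located 3D HU volumes (NCCT, CTA, CTV)
containing a straight vessel segment with an occluding clot, plus the clot
mask.  It stands in for a co-registered clinical acquisition: all three
phases live on the same grid, and misregistration can optionally be modelled
as an integer-voxel shift of the contrast phases.

The measurement procedure mirrors clinical practice: three 1 mm spherical
ROIs are placed evenly along the clot, each ROI is averaged per phase, and
the three ROI means are averaged to a single density per phase.

Coordinate convention: axis-aligned grid, 0-based indices, world origin at
the volume corner, voxel centres at ``(i + 0.5) * spacing``.  ROI membership
is voxel-centre-in-sphere (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import PhaseDensities
from .errors import ConfigurationError, PlacementError, SamplingError

__all__ = [
    "PhantomStudy",
    "ROISpec",
    "simulate_phantom",
    "place_rois",
    "mean_roi_density",
    "measure_phantom",
    "save_phantom",
    "load_phantom",
]

PHASES = ("ncct", "cta", "ctv")

#: Studies below this in-plane resolution were excluded from analysis;
#: phantoms must not be generated coarser than the clinical quality bar.
MAX_VOXEL_MM = 0.8

_MIN_VOXEL_MM = 0.2


@dataclass
class PhantomStudy:
    """Three co-located HU volumes with a clot mask.

    All arrays share one shape; ``voxel_spacing`` is mm per axis.
    """

    ncct: np.ndarray
    cta: np.ndarray
    ctv: np.ndarray
    clot_mask: np.ndarray
    voxel_spacing: tuple[float, float, float]
    noise_sd: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.ncct.shape, self.cta.shape, self.ctv.shape, self.clot_mask.shape}
        if len(shapes) != 1:
            raise ConfigurationError(f"phase volumes and mask must share a shape, got {shapes}")
        if not np.any(self.clot_mask):
            raise ConfigurationError("clot mask is empty")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3:
            raise ConfigurationError("voxel_spacing must have three components")
        for s in self.voxel_spacing:
            if not (_MIN_VOXEL_MM <= s <= MAX_VOXEL_MM):
                raise ConfigurationError(
                    f"voxel spacing {s} mm outside supported range "
                    f"[{_MIN_VOXEL_MM}, {MAX_VOXEL_MM}] mm"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ncct.shape

    def volume(self, phase: str) -> np.ndarray:
        if phase not in PHASES:
            raise KeyError(f"unknown phase {phase!r}; expected one of {PHASES}")
        return getattr(self, phase)

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres, optionally masked."""
        if mask is None:
            mask = np.ones(self.shape, dtype=bool)
        idx = np.argwhere(mask).astype(float)
        return (idx + 0.5) * np.asarray(self.voxel_spacing)


@dataclass(frozen=True)
class ROISpec:
    """A spherical ROI given by its physical centre (mm) and diameter (mm)."""

    center: tuple[float, float, float]
    diameter: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")


def simulate_phantom(
    clot_hu: Sequence[float],
    clot_length_mm: float = 18.0,
    vessel_radius_mm: float = 2.0,
    voxel_mm: float = 0.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
    background_hu: float = 35.0,
    lumen_hu: Sequence[float] = (40.0, 400.0, 250.0),
    margin_mm: float = 3.0,
    misregistration_voxels: Sequence[int] | None = None,
) -> PhantomStudy:
    """Build a three-phase phantom with a clot inside a straight vessel.

    Parameters
    ----------
    clot_hu:
        Nominal mean clot density per phase ``(ncct, cta, ctv)``.
    clot_length_mm:
        Clot length along the vessel axis; must be at least 3 mm (the
        shortest clot the measurement procedure supports).
    vessel_radius_mm:
        Radius of the cylindrical vessel.
    voxel_mm:
        Isotropic voxel spacing (default 0.5 mm, well inside the 0.8 mm
        clinical quality bar).
    noise_sd:
        SD of additive Gaussian noise (HU), applied independently per phase
        over the whole volume.  Zero gives exact nominal values.
    seed:
        Seed for the noise generator; fixed seed gives identical volumes.
    background_hu:
        Parenchyma value on all phases.
    lumen_hu:
        Patent-lumen value per phase (contrast opacifies CTA/CTV).
    misregistration_voxels:
        Optional integer-voxel shift applied to the CTA and CTV volumes to
        emulate residual registration error; vacated voxels are filled with
        ``background_hu``.
    """
    clot_hu = tuple(float(v) for v in clot_hu)
    lumen_hu = tuple(float(v) for v in lumen_hu)
    if len(clot_hu) != 3 or len(lumen_hu) != 3:
        raise ConfigurationError("clot_hu and lumen_hu must each have three phase values")
    if clot_length_mm < 3.0:
        raise ConfigurationError(f"clot length must be >= 3 mm, got {clot_length_mm}")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")

    nx = int(np.ceil((clot_length_mm + 2 * margin_mm) / voxel_mm))
    nyz = int(np.ceil((2 * vessel_radius_mm + 2 * margin_mm) / voxel_mm))
    if max(nx, nyz) > 512:
        raise ConfigurationError(
            f"geometry does not fit a reasonable grid (requested {nx}x{nyz}x{nyz})"
        )

    # Voxel-centre coordinates.
    x = (np.arange(nx) + 0.5) * voxel_mm
    yz = (np.arange(nyz) + 0.5) * voxel_mm
    cy = cz = nyz * voxel_mm / 2.0
    X, Y, Z = np.meshgrid(x, yz, yz, indexing="ij")

    vessel = (Y - cy) ** 2 + (Z - cz) ** 2 <= vessel_radius_mm**2
    clot = vessel & (X >= margin_mm) & (X < margin_mm + clot_length_mm)
    if not np.any(clot):
        raise ConfigurationError("clot geometry produced no voxels; refine the grid")

    rng = np.random.default_rng(seed)
    volumes = {}
    for k, phase in enumerate(PHASES):
        vol = np.full((nx, nyz, nyz), background_hu, dtype=float)
        vol[vessel] = lumen_hu[k]
        vol[clot] = clot_hu[k]
        if noise_sd > 0:
            vol += rng.normal(0.0, noise_sd, size=vol.shape)
        volumes[phase] = vol

    if misregistration_voxels is not None:
        shift = tuple(int(s) for s in misregistration_voxels)
        for phase in ("cta", "ctv"):
            volumes[phase] = _shift_volume(volumes[phase], shift, fill=background_hu)

    return PhantomStudy(
        ncct=volumes["ncct"],
        cta=volumes["cta"],
        ctv=volumes["ctv"],
        clot_mask=clot,
        voxel_spacing=(voxel_mm, voxel_mm, voxel_mm),
        noise_sd=noise_sd,
        meta={
            "clot_hu": clot_hu,
            "clot_length_mm": clot_length_mm,
            "vessel_radius_mm": vessel_radius_mm,
            "seed": seed,
        },
    )


def _shift_volume(vol: np.ndarray, shift: tuple[int, int, int], fill: float) -> np.ndarray:
    out = np.full_like(vol, fill)
    src = []
    dst = []
    for s, n in zip(shift, vol.shape):
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = vol[tuple(src)]
    return out


def place_rois(study: PhantomStudy, n: int = 3, diameter_mm: float = 1.0) -> list[ROISpec]:
    """Place ``n`` ROIs evenly along the clot centreline.

    The centreline direction is the principal axis of the clot-mask voxel
    cloud.  ROI centres sit at arc fractions ``(2k - 1) / (2n)`` of the
    clot's physical extent, so ``n`` ROIs of diameter ``d`` fit without
    overlap exactly when the clot is at least ``n * d`` long.  Each centre is
    the centroid of the nearby mask slab, snapped onto a mask voxel centre if
    the clot curves away from the straight chord.
    """
    if n < 1:
        raise ValueError("need at least one ROI")
    pts = study.voxel_centers(study.clot_mask)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if len(pts) == 1:
        axis = np.array([1.0, 0.0, 0.0])
    else:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    t = centered @ axis
    # Physical extent: span of voxel centres plus one voxel footprint along the axis.
    h = float(np.abs(axis) @ np.asarray(study.voxel_spacing))
    length = float(t.max() - t.min()) + h
    if length + 1e-9 < n * diameter_mm:
        raise PlacementError(
            f"clot extent {length:.2f} mm too short for {n} non-overlapping "
            f"{diameter_mm:.2f} mm ROIs"
        )
    t_start = float(t.min()) - h / 2.0
    spacing = np.asarray(study.voxel_spacing)
    half_diag = float(np.linalg.norm(spacing)) / 2.0
    rois = []
    for k in range(1, n + 1):
        target = t_start + length * (2 * k - 1) / (2 * n)
        slab_halfwidth = max(diameter_mm / 2.0, h)
        slab = np.abs(t - target) <= slab_halfwidth
        if not np.any(slab):
            slab = np.abs(t - target) == np.abs(t - target).min()
        center = pts[slab].mean(axis=0)
        # Guarantee the centre lies on the clot: snap to the nearest mask
        # voxel centre when the slab centroid falls off a curved clot.
        d2 = np.sum((pts - center) ** 2, axis=1)
        nearest = pts[int(np.argmin(d2))]
        if np.sqrt(d2.min()) > half_diag:
            center = nearest
        center = tuple(float(c) for c in center)
        _check_in_bounds(study, center, diameter_mm)
        rois.append(ROISpec(center=center, diameter=diameter_mm))
    return rois


def _check_in_bounds(study: PhantomStudy, center: tuple[float, float, float], diameter: float) -> None:
    extent = np.asarray(study.shape) * np.asarray(study.voxel_spacing)
    c = np.asarray(center)
    r = diameter / 2.0
    if np.any(c - r < -1e-9) or np.any(c + r > extent + 1e-9):
        raise PlacementError(f"ROI sphere at {center} (d={diameter} mm) exceeds volume bounds")


def mean_roi_density(study: PhantomStudy, rois: Sequence[ROISpec]) -> PhaseDensities:
    """Average each ROI per phase, then average the ROI means.

    Returns the per-phase result as :class:`PhaseDensities`.  An ROI sphere
    containing no voxel centres raises :class:`SamplingError`.
    """
    if not rois:
        raise SamplingError("no ROIs supplied")
    centers = study.voxel_centers()
    flat = {phase: study.volume(phase).ravel() for phase in PHASES}
    roi_means = {phase: [] for phase in PHASES}
    for roi in rois:
        d2 = np.sum((centers - np.asarray(roi.center)) ** 2, axis=1)
        inside = d2 <= (roi.diameter / 2.0) ** 2 + 1e-12
        if not np.any(inside):
            raise SamplingError(f"ROI at {roi.center} (d={roi.diameter} mm) contains no voxels")
        for phase in PHASES:
            roi_means[phase].append(float(flat[phase][inside].mean()))
    return PhaseDensities(
        ncct_hu=float(np.mean(roi_means["ncct"])),
        cta_hu=float(np.mean(roi_means["cta"])),
        ctv_hu=float(np.mean(roi_means["ctv"])),
    )


def measure_phantom(study: PhantomStudy, n_rois: int = 3, diameter_mm: float = 1.0) -> PhaseDensities:
    """Convenience: place ROIs along the clot and return the averaged densities."""
    return mean_roi_density(study, place_rois(study, n=n_rois, diameter_mm=diameter_mm))


# ---------------------------------------------------------------------------
# NIfTI I/O

def _affine(study_spacing: Sequence[float]) -> np.ndarray:
    # Voxel centres at (i + 0.5) * spacing: scale by spacing, offset half a voxel.
    spacing = np.asarray(study_spacing, dtype=float)
    aff = np.diag(np.append(spacing, 1.0))
    aff[:3, 3] = spacing / 2.0
    return aff


def save_phantom(study: PhantomStudy, directory: str | Path) -> dict[str, Path]:
    """Write the three phase volumes and clot mask as NIfTI files."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.voxel_spacing)
    paths = {}
    for phase in PHASES:
        p = directory / f"{phase}.nii.gz"
        nib.save(nib.Nifti1Image(study.volume(phase).astype(np.float32), aff), p)
        paths[phase] = p
    p = directory / "clot_mask.nii.gz"
    nib.save(nib.Nifti1Image(study.clot_mask.astype(np.uint8), aff), p)
    paths["clot_mask"] = p
    return paths


def load_phantom(
    ncct: str | Path,
    cta: str | Path,
    ctv: str | Path,
    clot_mask: str | Path,
    noise_sd: float = 0.0,
) -> PhantomStudy:
    """Load a phantom from NIfTI volumes; spacing is read from the headers."""
    import nibabel as nib

    imgs = {name: nib.load(str(p)) for name, p in
            [("ncct", ncct), ("cta", cta), ("ctv", ctv), ("clot_mask", clot_mask)]}
    spacing = tuple(float(z) for z in imgs["ncct"].header.get_zooms()[:3])
    return PhantomStudy(
        ncct=np.asarray(imgs["ncct"].dataobj, dtype=float),
        cta=np.asarray(imgs["cta"].dataobj, dtype=float),
        ctv=np.asarray(imgs["ctv"].dataobj, dtype=float),
        clot_mask=np.asarray(imgs["clot_mask"].dataobj) > 0,
        voxel_spacing=spacing,
        noise_sd=noise_sd,
    )
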