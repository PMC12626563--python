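"""Tumor shape features and a first-order intensity summary.

Shape features follow the standard radiomics constructions: volume from the
voxel count, surface from the marching-cubes iso-surface at level 0.5,
sphericity ``pi^(1/3) * (6V)^(2/3) / A`` (1 for a perfect sphere),
compactness ``A / V``, axis lengths from the eigen-decomposition of the
voxel-coordinate covariance (``4 * sqrt(lambda)``), maximum 3D diameter as
the largest pairwise distance between surface vertices.

Flatness here is ``major / medium`` axis length, a ratio >= 1 that grows as
the tumor flattens — note this is the reciprocal orientation of the
``minor / major`` flatness some radiomics tools report; the risk score that
consumes it was fitted to this >= 1 convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .mask_io import MORPHOLOGY_COLUMNS
from .vessel_geometry import EmptyMaskError


class DegenerateShapeError(ValueError):
    """Tumor voxels do not span three dimensions."""


@dataclass
class MorphologySet:
    T_surface: float  # mm^2
    T_volume: float  # mm^3
    T_sphere: float  # dimensionless, (0, 1] up to mesh tolerance
    T_compact: float  # mm^-1
    T_maxD: float  # mm
    T_majorAxis: float  # mm
    T_mediumAxis: float  # mm
    T_minorAxis: float  # mm
    T_flat: float  # major / medium, >= 1
    firstorder: Optional[dict] = None

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in MORPHOLOGY_COLUMNS}
        if self.firstorder:
            d.update({f"fo_{k}": v for k, v in self.firstorder.items()})
        return d


#: iso-surface estimation: the mask is supersampled 2x and lightly smoothed
#: before marching cubes. A raw binary mesh overstates a digital sphere's
#: area by ~8-10% (staircase); smoothing at the original scale shrinks small
#: convex bodies by ~sigma^2/r. Working at the doubled resolution keeps both
#: biases near 1% across radii 6-14 voxels.
MESH_UPSAMPLE = 2
MESH_SMOOTHING_SIGMA = 1.2  # in supersampled voxels


def _mesh(tumor: np.ndarray, spacing: Sequence[float]):
    bbox = ndimage.find_objects(tumor.astype(np.uint8))[0]
    crop = tumor[bbox]
    fine = ndimage.zoom(crop.astype(np.uint8), MESH_UPSAMPLE, order=0)
    smooth = ndimage.gaussian_filter(
        np.pad(fine, 3).astype(float), sigma=MESH_SMOOTHING_SIGMA
    )
    if smooth.max() <= 0.5:  # tiny blobs smooth below the level; mesh raw
        smooth = np.pad(fine, 3).astype(float)
    fine_spacing = tuple(s / MESH_UPSAMPLE for s in spacing)
    verts, faces, *_ = measure.marching_cubes(
        smooth, level=0.5, spacing=fine_spacing
    )
    offset = np.array([sl.start for sl in bbox], dtype=float) * np.asarray(
        spacing, dtype=float
    ) - 3 * np.asarray(fine_spacing, dtype=float)
    return verts + offset, faces


def _mesh_vertices(tumor: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    return _mesh(tumor, spacing)[0]


def mesh_surface_volume(
    tumor: np.ndarray, spacing: Sequence[float] = (1.0, 1.0, 1.0)
) -> tuple[float, float]:
    """(surface mm^2, volume mm^3) of a binary tumor mask."""
    tumor = np.asarray(tumor).astype(bool)
    if tumor.sum() == 0:
        raise EmptyMaskError("tumor mask is empty")
    spacing = tuple(float(s) for s in spacing)
    volume = float(tumor.sum()) * float(np.prod(spacing))
    verts, faces = _mesh(tumor, spacing)
    surface = float(measure.mesh_surface_area(verts, faces))
    return surface, volume


def shape_scores(T_surface: float, T_volume: float) -> tuple[float, float]:
    """(sphericity, compactness) from surface area and volume.

    Sphericity is the ratio of the surface of the equal-volume sphere to the
    actual surface; compactness is simply surface over volume (units 1/mm).
    """
    if T_surface <= 0 or T_volume <= 0:
        raise ValueError("surface and volume must be positive")
    sphere = np.pi ** (1.0 / 3.0) * (6.0 * T_volume) ** (2.0 / 3.0) / T_surface
    compact = T_surface / T_volume
    return float(sphere), float(compact)


def principal_axes_diameters(
    tumor: np.ndarray, spacing: Sequence[float] = (1.0, 1.0, 1.0)
) -> tuple[float, float, float, float, float]:
    """(T_maxD, major, medium, minor axis lengths, flatness) in mm.

    Axis lengths are ``4 * sqrt(eigenvalue)`` of the physical-coordinate
    covariance of the tumor voxels (the fitted-ellipsoid convention); the
    maximum 3D diameter is the exact largest pairwise distance between
    iso-surface vertices, computed on the convex hull for speed.
    """
    tumor = np.asarray(tumor).astype(bool)
    if tumor.sum() == 0:
        raise EmptyMaskError("tumor mask is empty")
    coords = np.argwhere(tumor) * np.asarray(spacing, dtype=float)
    if coords.shape[0] < 4 or np.linalg.matrix_rank(coords - coords.mean(0)) < 3:
        raise DegenerateShapeError("tumor voxels are coplanar or too few")
    cov = np.cov(coords.T, bias=True)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    major, medium, minor = (4.0 * np.sqrt(ev) for ev in eigvals)
    flat = major / medium

    verts = _mesh_vertices(tumor, spacing)
    hull_pts = verts[ConvexHull(verts).vertices]
    max_d = float(pdist(hull_pts).max())
    return max_d, float(major), float(medium), float(minor), float(flat)


def first_order_intensity(
    intensity: np.ndarray, tumor: np.ndarray, n_bins: int = 64
) -> dict:
    """First-order intensity statistics over the tumor voxels.

    Variance/skewness/kurtosis use the population convention (kurtosis is the
    Pearson ratio m4/m2^2, 3 for a Gaussian); entropy and uniformity come from
    an ``n_bins`` histogram with base-2 logs.
    """
    intensity = np.asarray(intensity, dtype=float)
    tumor = np.asarray(tumor).astype(bool)
    if intensity.shape != tumor.shape:
        raise ValueError("intensity grid differs from tumor grid")
    if tumor.sum() == 0:
        raise EmptyMaskError("tumor mask is empty")
    x = intensity[tumor]
    mean = float(x.mean())
    var = float(x.var(ddof=0))
    centred = x - mean
    if var > 0:
        skew = float((centred ** 3).mean() / var ** 1.5)
        kurt = float((centred ** 4).mean() / var ** 2)
    else:
        skew, kurt = 0.0, 0.0
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "min": float(x.min()),
        "max": float(x.max()),
        "range": float(x.max() - x.min()),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((x ** 2).sum()),
        "entropy": entropy,
        "uniformity": uniformity,
    }


def extract_morphology(
    tumor: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    intensity: Optional[np.ndarray] = None,
    n_bins: int = 64,
) -> MorphologySet:
    """All shape features (plus optional first-order stats) for one tumor."""
    surface, volume = mesh_surface_volume(tumor, spacing)
    sphere, compact = shape_scores(surface, volume)
    max_d, major, medium, minor, flat = principal_axes_diameters(tumor, spacing)
    fo = (
        first_order_intensity(intensity, tumor, n_bins)
        if intensity is not None else None
    )
    return MorphologySet(
        T_surface=surface, T_volume=volume, T_sphere=sphere, T_compact=compact,
        T_maxD=max_d, T_majorAxis=major, T_mediumAxis=medium,
        T_minorAxis=minor, T_flat=flat, firstorder=fo,
    )
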