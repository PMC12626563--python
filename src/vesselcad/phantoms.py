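"""Synthetic 3D vessel/tumor scenes with known geometric ground truth.

Phantoms stand in for patient imaging: digital tubes (straight, curved or
Y-shaped, optionally with a stenosis near the tumor) play the peripancreatic
vessels, and ellipsoids or angular shell sectors ("wraps") play the tumor.
Every generator records the exact generating parameters in a ``truth`` dict
from which the mask can be re-rendered bit-for-bit, so feature extractors can
be validated against analytic ground truth. A tabular generator draws
feature/label data from a logistic risk-score model for parameter-recovery
experiments.

Geometry conventions: isotropic 1 mm grid, axes (z, y, x), tubes run along z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mask_io import StructureSet, VESSEL_NAMES
from .risk_models import RiskScoreModel

DEFAULT_GRID = 96  # largest suite runs in minutes on one CPU at 96^3
#: default wrap-phantom vessel caliber: the 3-voxel contact tolerance smears
#: the measured sector edge by roughly asin(tau/r) to each side; a caliber of
#: 24 voxels keeps the total bias under ~14 degrees
WRAP_VESSEL_RADIUS = 24.0
WRAP_VESSEL_LENGTH = 40.0


class GeometryError(ValueError):
    """Requested phantom does not fit the grid."""


@dataclass
class PhantomScene:
    structures: StructureSet
    truth: dict


def _as_shape(grid) -> tuple[int, int, int]:
    if np.isscalar(grid):
        return (int(grid),) * 3
    return tuple(int(g) for g in grid)


def _render_tube(
    centerline: np.ndarray, radii: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Voxels within the local radius of a polyline centerline."""
    rmax = float(radii.max())
    lo = np.maximum(np.floor(centerline.min(0) - rmax - 1).astype(int), 0)
    hi = np.minimum(
        np.ceil(centerline.max(0) + rmax + 2).astype(int), np.array(shape)
    )
    if (hi <= lo).any():
        raise GeometryError("tube lies outside the grid")
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[d], hi[d]) for d in range(3)), indexing="ij"
    )
    coords = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3).astype(float)
    tree = cKDTree(centerline)
    dist, idx = tree.query(coords, k=1)
    inside = dist <= radii[idx]
    mask = np.zeros(shape, dtype=bool)
    sub = inside.reshape(hi[0] - lo[0], hi[1] - lo[1], hi[2] - lo[2])
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return mask


def _centerline(
    shape_kind: str, length: float, center_yx: tuple[float, float],
    z0: float, curve_amp: float = 6.0, step: float = 0.5,
) -> np.ndarray:
    cy, cx = center_yx
    t = np.arange(0.0, length + step / 2, step)
    if shape_kind == "straight":
        return np.stack([z0 + t, np.full_like(t, cy), np.full_like(t, cx)], 1)
    if shape_kind == "curved":
        y = cy + curve_amp * np.sin(np.pi * t / length)
        return np.stack([z0 + t, y, np.full_like(t, cx)], 1)
    if shape_kind == "Y":
        half = length / 2.0
        trunk_t = t[t <= half]
        trunk = np.stack(
            [z0 + trunk_t, np.full_like(trunk_t, cy), np.full_like(trunk_t, cx)], 1
        )
        limb_t = np.arange(step, half + step / 2, step)
        d1 = np.array([1.0, 0.6, 0.0])
        d1 /= np.linalg.norm(d1)
        d2 = np.array([1.0, -0.6, 0.0])
        d2 /= np.linalg.norm(d2)
        origin = np.array([z0 + half, cy, cx])
        limb1 = origin + limb_t[:, None] * d1
        limb2 = origin + limb_t[:, None] * d2
        return np.concatenate([trunk, limb1, limb2])
    raise ValueError(f"unknown vessel shape {shape_kind!r}")


def render_vessel_truth(truth: dict) -> np.ndarray:
    """Re-render a vessel mask exactly from its truth record."""
    mask = _render_tube(
        np.asarray(truth["centerline"], dtype=float),
        np.asarray(truth["radii"], dtype=float),
        tuple(truth["grid"]),
    )
    clip = truth.get("z_clip")
    if clip is not None:  # flat end caps for straight tubes
        z = np.arange(mask.shape[0])
        outside = (z < clip[0] - 0.5) | (z > clip[1] + 0.5)
        mask[outside] = False
    return mask


def make_vessel_phantom(
    shape: str = "straight",
    length: float = 60.0,
    radius_profile=4.0,
    grid=DEFAULT_GRID,
    seed: int = 0,
    center_yx: Optional[tuple[float, float]] = None,
    z0: Optional[float] = None,
) -> tuple[np.ndarray, dict]:
    """A digital tube with known centerline and per-arclength radius.

    ``radius_profile`` may be a scalar, a per-sample array, or a callable of
    normalized arclength in [0, 1]. Returns (mask, truth); the truth record
    re-renders the mask deterministically.
    """
    gshape = _as_shape(grid)
    if center_yx is None:
        center_yx = (gshape[1] / 2.0, gshape[2] / 2.0)
    if z0 is None:
        z0 = (gshape[0] - length) / 2.0
    cl = _centerline(shape, length, center_yx, z0)
    t_norm = np.linspace(0.0, 1.0, len(cl))
    if callable(radius_profile):
        radii = np.asarray([radius_profile(t) for t in t_norm], dtype=float)
    elif np.isscalar(radius_profile):
        radii = np.full(len(cl), float(radius_profile))
    else:
        rp = np.asarray(radius_profile, dtype=float)
        radii = np.interp(t_norm, np.linspace(0, 1, len(rp)), rp)
    if radii.min() < 2:
        raise GeometryError("vessel radius must be >= 2 voxels")
    lo = cl - radii[:, None]
    hi = cl + radii[:, None]
    if shape == "straight":  # flat caps: no axial overhang beyond the ends
        lo[:, 0] = cl[:, 0]
        hi[:, 0] = cl[:, 0]
    if (lo < -0.5).any() or (hi > np.array(gshape) - 0.5).any():
        raise GeometryError("tube exceeds the grid")
    truth = {
        "kind": "vessel", "shape": shape, "length": float(length),
        "centerline": cl, "radii": radii, "grid": list(gshape),
        "seed": int(seed),
    }
    if shape == "straight":
        truth["z_clip"] = [float(z0), float(z0 + length)]
    return render_vessel_truth(truth), truth


def render_tumor_truth(truth: dict) -> np.ndarray:
    shape = tuple(truth["grid"])
    if truth["tumor_kind"] == "ellipsoid":
        center = np.asarray(truth["center"], dtype=float)
        semi = np.asarray(truth["semi_axes"], dtype=float)
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        q = (
            ((zz - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((xx - center[2]) / semi[2]) ** 2
        )
        return q <= 1.0
    if truth["tumor_kind"] == "wrap":
        cy, cx = truth["axis_yx"]
        r_in = float(truth["inner_radius"])
        thick = float(truth["thickness"])
        psi = float(truth["psi_deg"])
        theta0 = float(truth["theta0_deg"])
        z_lo, z_hi = truth["z_span"]
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        rho = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        ang = np.degrees(np.arctan2(xx - cx, yy - cy)) % 360.0
        rel = (ang - theta0) % 360.0
        in_sector = rel <= psi if psi < 360 else np.ones_like(rel, dtype=bool)
        return (
            (zz >= z_lo) & (zz <= z_hi)
            & (rho >= r_in) & (rho <= r_in + thick)
            & in_sector
        )
    raise ValueError(f"unknown tumor kind {truth['tumor_kind']!r}")


def make_tumor_phantom(
    kind: str,
    params: dict,
    vessel_truth: Optional[dict] = None,
    grid=DEFAULT_GRID,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """An ellipsoidal tumor, or a shell sector wrapping a vessel.

    Wrap parameters: ``psi_deg`` in (0, 360], angular span of the shell;
    ``gap`` (radial clearance from the vessel surface, default 1 so contact
    within the 3-voxel tolerance is guaranteed); ``thickness`` (default 2);
    ``z_span`` (axial extent, default 20 voxels centered on the vessel).
    The wrapped vessel must be a straight tube (truth from
    :func:`make_vessel_phantom`).
    """
    gshape = _as_shape(grid)
    if kind == "ellipsoid":
        truth = {
            "kind": "tumor", "tumor_kind": "ellipsoid",
            "center": list(map(float, params["center"])),
            "semi_axes": list(map(float, params["semi_axes"])),
            "grid": list(gshape), "seed": int(seed),
        }
        return render_tumor_truth(truth), truth
    if kind == "wrap":
        psi = float(params["psi_deg"])
        if not 0 < psi <= 360:
            raise ValueError("wrap angle psi must lie in (0, 360]")
        if vessel_truth is None or vessel_truth.get("shape") != "straight":
            raise ValueError("wrap tumors require a straight vessel truth")
        cl = np.asarray(vessel_truth["centerline"])
        cy, cx = float(cl[0, 1]), float(cl[0, 2])
        radius = float(np.asarray(vessel_truth["radii"]).max())
        gap = float(params.get("gap", 1.0))
        thickness = float(params.get("thickness", 2.0))
        z_mid = float(cl[:, 0].mean())
        span = float(params.get("span", 20.0))
        z_span = params.get(
            "z_span", (z_mid - span / 2.0, z_mid + span / 2.0)
        )
        truth = {
            "kind": "tumor", "tumor_kind": "wrap",
            "axis_yx": [cy, cx],
            "inner_radius": radius + gap,
            "thickness": thickness,
            "psi_deg": psi,
            "theta0_deg": float(params.get("theta0_deg", 0.0)),
            "z_span": [float(z_span[0]), float(z_span[1])],
            "grid": list(gshape), "seed": int(seed),
        }
        return render_tumor_truth(truth), truth
    raise ValueError(f"unknown tumor kind {kind!r}")


def make_scene(
    n_vessels: int = 2,
    stenosis: Optional[float] = None,
    seed: int = 0,
    grid=DEFAULT_GRID,
    vessel_radius: float = 4.0,
    tumor_semi_axes: tuple[float, float, float] = (8.0, 6.0, 6.0),
    tumor_gap: float = 1.0,
) -> PhantomScene:
    """Compose straight vessels and one ellipsoidal tumor near the first.

    Vessels take names from the five-vessel vocabulary in order. ``stenosis``
    multiplies the first vessel's radius inside the tumor-proximal axial
    segment (|z - z_tumor| <= 10), emulating tumor-induced narrowing. All
    generating parameters are retained in ``truth``.
    """
    if not 1 <= n_vessels <= len(VESSEL_NAMES):
        raise ValueError("n_vessels must be between 1 and 5")
    gshape = _as_shape(grid)
    length = gshape[0] - 26.0
    z0 = 13.0
    z_mid = z0 + length / 2.0
    y_line = 30.0
    x_positions = [30.0 + 15.0 * i for i in range(n_vessels)]
    if x_positions[-1] + vessel_radius + 2 > gshape[2]:
        raise GeometryError("vessel placement exceeds the grid")

    tumor_center = (
        z_mid,
        y_line + vessel_radius + tumor_semi_axes[1] + tumor_gap,
        x_positions[0],
    )

    def radius_fn(t: float) -> float:
        z = z0 + t * length
        if stenosis is not None and abs(z - z_mid) <= 10.0:
            return vessel_radius * float(stenosis)
        return vessel_radius

    vessels: dict[str, np.ndarray] = {}
    vessel_truths: dict[str, dict] = {}
    for i, x in enumerate(x_positions):
        name = VESSEL_NAMES[i]
        profile = radius_fn if i == 0 else vessel_radius
        mask, truth = make_vessel_phantom(
            "straight", length=length, radius_profile=profile,
            grid=gshape, seed=seed, center_yx=(y_line, x), z0=z0,
        )
        vessels[name] = mask
        vessel_truths[name] = truth

    tumor, tumor_truth = make_tumor_phantom(
        "ellipsoid",
        {"center": tumor_center, "semi_axes": tumor_semi_axes},
        grid=gshape, seed=seed,
    )
    for name, v in vessels.items():
        vessels[name] = v & ~tumor  # tumor takes precedence where they meet

    structures = StructureSet(
        tumor=tumor, vessels=vessels, spacing=(1.0, 1.0, 1.0)
    )
    truth = {
        "seed": int(seed), "grid": list(gshape),
        "stenosis": None if stenosis is None else float(stenosis),
        "vessels": vessel_truths, "tumor": tumor_truth,
    }
    return PhantomScene(structures=structures, truth=truth)


def make_blob_phantom(
    grid=48, seed: int = 0, n_balls: int = 4, r_range=(4.0, 9.0)
) -> np.ndarray:
    """A random connected blob (union of overlapping balls); test fodder."""
    gshape = _as_shape(grid)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB10B]))
    centers = [np.array(gshape, dtype=float) / 2.0]
    radii = [rng.uniform(*r_range)]
    for _ in range(n_balls - 1):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        step = rng.uniform(0.5, 1.0) * radii[-1]
        centers.append(centers[-1] + direction * step)
        radii.append(rng.uniform(*r_range))
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in gshape), indexing="ij")
    mask = np.zeros(gshape, dtype=bool)
    for c, r in zip(centers, radii):
        mask |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r**2
    return mask


DEFAULT_DISTRIBUTIONS: dict[str, Callable] = {
    "T_flat": lambda rng, n: rng.uniform(1.0, 1.6, n),
    "T_sphere": lambda rng, n: rng.uniform(0.4, 1.0, n),
}


def simulate_feature_table(
    model: RiskScoreModel,
    n: int,
    feature_distributions: Optional[dict[str, Callable]] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw features i.i.d. and outcomes from the model's logistic law.

    Default feature laws: ``T_flat ~ U(1.0, 1.6)``, ``T_sphere ~ U(0.4, 1.0)``
    and standard normal for (standardized) features without a stated law.
    Returns (feature table, binary outcomes), fully determined by ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dists = dict(DEFAULT_DISTRIBUTIONS)
    if feature_distributions:
        dists.update(feature_distributions)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFEA7]))
    data = {}
    for f in model.feature_names:
        draw = dists.get(f, lambda r, m: r.standard_normal(m))
        data[f] = np.asarray(draw(rng, n), dtype=float)
    X = pd.DataFrame(data)
    probs = model.predict(X.to_numpy())
    y = (rng.uniform(size=n) < probs).astype(int)
    return X, y
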