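"""Interzygomatic-plane construction and proptosis measurement.

The 3-D method mirrors the four-stage workflow of the reconstruction
software: given a segmented eyeball mask and three orbital-rim reference
points, it (1) fits the interzygomatic plane through the points with the
normal oriented anteriorly, (2) finds the center of mass of the junction of
the eyeball and the plane, (3) casts a ray from that centroid along the
plane normal to the last crossing of the eyeball surface, and (4) reports
the ray length in mm as the degree of proptosis.

The conventional 2-D method is the perpendicular distance from the corneal
apex to the interzygomatic line drawn between the lateral orbital rims on a
single axial slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .volume_io import BinaryMask

__all__ = [
    "InterzygomaticPlane",
    "ProptosisMeasurement",
    "fit_plane",
    "junction_centroid",
    "cast_ray_to_surface",
    "measure_proptosis_3d",
    "measure_proptosis_2d",
]

#: minimum triangle area (mm^2) below which reference points are collinear
_COLLINEAR_AREA = 1e-6


@dataclass
class InterzygomaticPlane:
    """Oriented plane: anchor point (mm) + anterior-pointing unit normal."""

    anchor: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            self.normal = self.normal / n

    def signed_distance(self, points) -> np.ndarray:
        """Signed mm distance(s); positive on the anterior side."""
        p = np.asarray(points, dtype=float)
        return (p - self.anchor) @ self.normal

    def project(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        d = self.signed_distance(p)
        return p - np.multiply.outer(d, self.normal)


@dataclass
class ProptosisMeasurement:
    """One proptosis reading: side, method tag, length and supporting points."""

    side: str
    method: str  # "software3d" | "ct2d"
    length_mm: float
    centroid: np.ndarray | None = None
    exit_point: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {"side": self.side, "method": self.method, "length_mm": round(float(self.length_mm), 2)}
        if self.centroid is not None:
            d["centroid"] = [float(x) for x in self.centroid]
        if self.exit_point is not None:
            d["exit_point"] = [float(x) for x in self.exit_point]
        return d


def fit_plane(points, anterior_axis=(0.0, 1.0, 0.0)) -> InterzygomaticPlane:
    """Fit the interzygomatic plane through three orbital-rim points.

    The normal is the normalized cross product of two edge vectors, flipped
    if needed so that it points along ``anterior_axis``; the anchor is the
    centroid of the three points.

    Raises
    ------
    ValueError
        If the points are collinear (triangle area <= 1e-6 mm^2) or the
        anterior axis is orthogonal to the plane normal (orientation
        undefined).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (3, 3):
        raise ValueError("exactly three 3-D reference points are required")
    e1, e2 = pts[1] - pts[0], pts[2] - pts[0]
    cr = np.cross(e1, e2)
    area = 0.5 * np.linalg.norm(cr)
    if area <= _COLLINEAR_AREA:
        raise ValueError("reference points are collinear; cannot define a plane")
    normal = cr / np.linalg.norm(cr)
    ant = np.asarray(anterior_axis, dtype=float)
    ant = ant / np.linalg.norm(ant)
    s = normal @ ant
    if abs(s) < 1e-12:
        raise ValueError("anterior axis lies in the plane; cannot orient the normal")
    if s < 0:
        normal = -normal
    return InterzygomaticPlane(anchor=pts.mean(axis=0), normal=normal)


def junction_centroid(mask: BinaryMask, plane: InterzygomaticPlane) -> np.ndarray:
    """Center of mass of the eyeball/plane junction, on the plane.

    The junction is the set of mask voxels whose center lies within half the
    smallest voxel spacing of the plane; the mean of those voxel centers is
    projected onto the plane so the result satisfies the plane equation
    exactly.
    """
    idx = np.argwhere(mask.data > 0)
    if idx.size == 0:
        raise ValueError("mask is empty")
    centers = mask.voxel_to_world(idx)
    half = 0.5 * float(np.min(mask.spacing))
    d = plane.signed_distance(centers)
    in_slab = np.abs(d) <= half
    if not np.any(in_slab):
        raise ValueError(
            "empty junction: the interzygomatic plane does not pass through "
            "the segmented eyeball"
        )
    return plane.project(centers[in_slab].mean(axis=0))


def _sample_mask(mask: BinaryMask, world_points: np.ndarray) -> np.ndarray:
    """Trilinear mask occupancy at world points; outside the grid -> 0."""
    vox = mask.world_to_voxel(world_points)
    return map_coordinates(
        mask.data.astype(np.float64), vox.T, order=1, mode="constant", cval=0.0
    )


def cast_ray_to_surface(
    mask: BinaryMask,
    origin,
    direction,
    step: float | None = None,
    refine_tol: float = 0.01,
) -> np.ndarray:
    """March a ray through the mask and return the last surface exit point.

    Occupancy is sampled by trilinear interpolation of the {0,1} mask and
    thresholded at 0.5.  The ray is marched from ``origin`` along
    ``direction`` in steps of a quarter of the smallest voxel spacing; the
    *last* inside-to-outside crossing before occupancy stays below 0.5 for
    the rest of the grid is refined by bisection to better than
    ``refine_tol`` mm.

    Raises
    ------
    ValueError
        If the origin lies outside the grid or the ray never enters the mask.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    vox0 = mask.world_to_voxel(origin)
    shape = np.asarray(mask.shape)
    if np.any(vox0 < -0.5) or np.any(vox0 > shape - 0.5):
        raise ValueError("ray origin lies outside the volume grid")

    if step is None:
        step = float(np.min(mask.spacing)) / 4.0
    # grid diagonal bounds the longest possible traversal
    t_max = float(np.linalg.norm(shape * mask.spacing)) + step
    ts = np.arange(0.0, t_max, step)
    occ = _sample_mask(mask, origin + np.outer(ts, direction)) >= 0.5
    if not occ.any():
        raise ValueError("ray never enters the mask")

    inside_to_out = np.flatnonzero(occ[:-1] & ~occ[1:])
    if inside_to_out.size == 0:
        # still inside at the final sample: surface is at the grid edge
        i = len(ts) - 1
        return origin + ts[i] * direction
    i = int(inside_to_out[-1])

    lo, hi = ts[i], ts[i + 1]
    while hi - lo > refine_tol:
        mid = 0.5 * (lo + hi)
        if _sample_mask(mask, (origin + mid * direction)[None, :])[0] >= 0.5:
            lo = mid
        else:
            hi = mid
    return origin + 0.5 * (lo + hi) * direction


def measure_proptosis_3d(
    mask: BinaryMask,
    reference_points,
    anterior_axis=(0.0, 1.0, 0.0),
    side: str = "right",
) -> ProptosisMeasurement:
    """Full 3-D proptosis measurement from a segmented eyeball mask.

    Fits the interzygomatic plane through the three rim points, locates the
    junction centroid, casts the anterior normal ray to the eyeball surface
    and reports the centroid-to-exit length in mm.
    """
    plane = fit_plane(reference_points, anterior_axis)
    centroid = junction_centroid(mask, plane)
    exit_point = cast_ray_to_surface(mask, centroid, plane.normal)
    length = float(np.linalg.norm(exit_point - centroid))
    return ProptosisMeasurement(
        side=side,
        method="software3d",
        length_mm=length,
        centroid=centroid,
        exit_point=exit_point,
    )


def measure_proptosis_2d(rim_a, rim_b, cornea_apex, anterior=(0.0, 1.0)) -> float:
    """Single-slice CT proptosis: corneal apex to the interzygomatic line.

    All points are 2-D (mm) in one axial plane.  Returns the perpendicular
    distance from the apex to the line through the two lateral orbital rim
    points, signed positive when the apex lies on the anterior side of the
    line.
    """
    a = np.asarray(rim_a, dtype=float)
    b = np.asarray(rim_b, dtype=float)
    c = np.asarray(cornea_apex, dtype=float)
    e = b - a
    norm_e = np.linalg.norm(e)
    if norm_e < 1e-12:
        raise ValueError("coincident rim points: interzygomatic line undefined")
    # in-plane normal to the line, oriented toward anterior
    n = np.array([-e[1], e[0]]) / norm_e
    ant = np.asarray(anterior, dtype=float)
    s = n @ ant
    if abs(s) < 1e-12:
        raise ValueError("interzygomatic line is parallel to the anterior axis")
    if s < 0:
        n = -n
    return float((c - a) @ n)
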