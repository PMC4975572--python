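"""Idealized-cylinder geometry for peripheral myonuclei.

A muscle fibre is modelled as a circular cylinder segment of constant radius.
The axis is the principal axis of the nucleus cloud, the radius the mean
perpendicular distance of the nuclei to that axis (nuclei sit at the fibre
periphery), and the length the axial span of the nuclei.  Nuclei are then
described by unrolled-surface coordinates (z along the axis, θ around it) and
distances between them are measured on the surface.

Surface point sets are plain ``(n, 2)`` float arrays with columns ``[z, theta]``;
``SurfacePoint`` is a named tuple for scalar use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .errors import DegenerateGeometryError, InsufficientDataError, UndefinedAzimuthError

TWO_PI = 2.0 * np.pi

Metric = Literal["geodesic", "chord"]


class SurfacePoint(NamedTuple):
    """One nucleus in unrolled-cylinder coordinates."""

    z_axial: float
    theta: float


@dataclass(frozen=True)
class CylinderModel:
    """Fitted idealized cylinder segment.

    Parameters
    ----------
    origin
        Point on the axis at the low end of the segment (µm).
    axis
        Unit vector along the axis.
    radius
        Cylinder radius R (µm), > 0.
    length
        Segment length L (µm), > 0.
    """

    origin: np.ndarray
    axis: np.ndarray
    radius: float
    length: float

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        if origin.shape != (3,) or axis.shape != (3,):
            raise ValueError("origin and axis must be 3-vectors")
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector")
        if not (self.radius > 0 and self.length > 0):
            raise DegenerateGeometryError("radius and length must be positive")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axis", axis)

    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Right-handed in-plane basis (u, v) fixing the θ = 0 direction.

        u is the coordinate axis most orthogonal to the cylinder axis, projected
        into the cross-sectional plane; results downstream are invariant to this
        convention (only θ differences enter any distance).
        """
        k = int(np.argmin(np.abs(self.axis)))
        e = np.zeros(3)
        e[k] = 1.0
        u = e - np.dot(e, self.axis) * self.axis
        u /= np.linalg.norm(u)
        v = np.cross(self.axis, u)
        return u, v

    def surface_to_3d(self, points: np.ndarray) -> np.ndarray:
        """Embed surface coordinates back into 3D at radius R."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        u, v = self.frame()
        radial = np.cos(pts[:, 1])[:, None] * u + np.sin(pts[:, 1])[:, None] * v
        return self.origin + pts[:, 0][:, None] * self.axis + self.radius * radial


def _refine_axis(centred: np.ndarray, frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares cylinder axis: minimize the spread of perpendicular
    distances around their mean (i.e. fit a constant-radius cylinder).

    A plain principal-axis line chases sampling noise of the point cloud: its
    transverse position is set by the noisy centroid (error ~ R/√n), which
    distorts projected azimuths and biases the orderness null at moderate n.
    The cylinder criterion is instead conditioned by the radial scatter of the
    nuclei about the surface, typically ≪ R.

    Damped Gauss–Newton over the four identifiable parameters (transverse
    offset and tilt in the principal-axis frame, killing the two gauge
    freedoms of a line in space), with a fixed iteration budget and
    scale-equivariant step sizes so the result is a pure function of the
    input coordinates.
    """
    Y = centred @ frame.T  # rows: (axial, transverse u, transverse v)

    def perp_resid(p: np.ndarray) -> np.ndarray:
        c = np.array([0.0, p[0], p[1]])
        d = np.array([1.0, p[2], p[3]])
        d /= np.linalg.norm(d)
        rel = Y - c
        t = rel @ d
        r = np.linalg.norm(rel - np.outer(t, d), axis=1)
        return r - r.mean()

    p = np.zeros(4)
    r0 = np.linalg.norm(Y[:, 1:], axis=1).mean()
    span = Y[:, 0].max() - Y[:, 0].min()
    h = np.array([1e-7 * r0, 1e-7 * r0, 1e-7 * r0 / max(span, r0), 1e-7 * r0 / max(span, r0)])
    for _ in range(30):
        res = perp_resid(p)
        cols = []
        for j in range(4):
            dp = np.zeros(4)
            dp[j] = h[j]
            cols.append((perp_resid(p + dp) - perp_resid(p - dp)) / (2 * h[j]))
        J = np.column_stack(cols)
        A = J.T @ J
        A[np.diag_indices_from(A)] *= 1.0 + 1e-10
        try:
            step = np.linalg.solve(A, -J.T @ res)
        except np.linalg.LinAlgError:
            break
        p = p + step
    axis = np.array([1.0, p[2], p[3]])
    axis /= np.linalg.norm(axis)
    point = np.array([0.0, p[0], p[1]])
    # back to the original frame
    return frame.T @ point, frame.T @ axis


def fit_cylinder(nuclei: np.ndarray, *, min_radius: float = 0.5) -> CylinderModel:
    """Fit the idealized circular cylinder segment to nucleus coordinates.

    The axis starts from the direction of maximal variance through the
    centroid (closed-form, via SVD) and is refined by a least-squares
    constant-radius cylinder fit (for n ≥ 7; below that the refinement is
    underdetermined and the principal axis is kept).  The radius is the mean
    perpendicular distance of the nuclei to the axis.  The length applies the
    uniform-support correction to the axial span: L = span·(n+1)/(n−1), with
    the origin half the padding below the minimal projection, so the observed
    extremes sit where the extremes of n uniform draws on [0, L] are expected.
    Without this correction a pattern's own extremes would be pinned to the
    segment ends, inflating their nearest-neighbour distances relative to the
    uniform reference and biasing the orderness score upward by O(1/n).

    Parameters
    ----------
    nuclei
        ``(n, 3)`` coordinates in µm, n ≥ 4.
    min_radius
        Floor below which the fitted radius is considered degenerate
        (near-collinear input), in µm.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 nuclei.
    DegenerateGeometryError
        Collinear/near-collinear nuclei (fitted radius below ``min_radius``)
        or zero axial extent.
    """
    pts = np.asarray(nuclei, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("nuclei must be an (n, 3) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("nucleus coordinates must be finite")
    n = pts.shape[0]
    if n < 4:
        raise InsufficientDataError(f"cylinder fit needs >= 4 nuclei, got {n}")

    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, sv, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    base = centroid
    # refine only when identifiable (6 parameters) and not near-collinear,
    # where the cylinder criterion is ill-posed anyway
    if n >= 7 and sv[1] > 1e-9 * max(sv[0], 1.0):
        p0, axis = _refine_axis(centred, vt)
        base = centroid + p0
    # deterministic sign: largest-magnitude component positive
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
    axis = axis / np.linalg.norm(axis)

    rel = pts - base
    t = rel @ axis
    span = float(t.max() - t.min())
    perp = rel - np.outer(t, axis)
    radius = float(np.linalg.norm(perp, axis=1).mean())
    if radius < min_radius:
        raise DegenerateGeometryError(
            f"fitted radius {radius:.3g} µm below floor {min_radius} µm (near-collinear nuclei?)"
        )
    if span <= 0:
        raise DegenerateGeometryError("nuclei have zero axial extent")
    pad = span / (n - 1)
    length = span * (n + 1) / (n - 1)
    origin = base + (float(t.min()) - pad) * axis
    return CylinderModel(origin=origin, axis=axis, radius=radius, length=length)


def project_to_surface(
    nuclei: np.ndarray, cyl: CylinderModel, *, clamp_tol: float = 1e-6
) -> np.ndarray:
    """Project nuclei radially onto the cylinder surface.

    Returns an ``(n, 2)`` array ``[z, theta]`` with z clamped to [0, L] (within
    ``clamp_tol * L``) and θ wrapped to [0, 2π).  The radial distance of each
    nucleus is discarded: all points are treated as lying at radius R.

    Raises
    ------
    UndefinedAzimuthError
        A nucleus lies on the axis (azimuth undefined).
    ValueError
        A projection falls outside [0, L] by more than the clamp tolerance.
    """
    pts = np.atleast_2d(np.asarray(nuclei, dtype=float))
    rel = pts - cyl.origin
    t = rel @ cyl.axis
    tol = clamp_tol * cyl.length
    if t.min() < -tol or t.max() > cyl.length + tol:
        raise ValueError("axial projection outside the cylinder segment")
    z = np.clip(t, 0.0, cyl.length)

    perp = rel - np.outer(t, cyl.axis)
    r = np.linalg.norm(perp, axis=1)
    if np.any(r < 1e-9 * max(cyl.radius, 1.0)):
        raise UndefinedAzimuthError("a nucleus lies on the cylinder axis")
    u, v = cyl.frame()
    theta = np.arctan2(perp @ v, perp @ u) % TWO_PI
    return np.column_stack([z, theta])


def wrapped_angle(dtheta: np.ndarray) -> np.ndarray:
    """Shortest angular difference |Δθ| wrapped to [0, π]."""
    a = np.abs(np.asarray(dtheta)) % TWO_PI
    return np.minimum(a, TWO_PI - a)


def surface_distance(a, b, radius: float, *, metric: Metric = "geodesic"):
    """Distance between two surface points on a cylinder of the given radius.

    ``geodesic`` (default) is the Euclidean distance on the unrolled rectangle,
    sqrt(Δz² + (R·Δθ_wrapped)²); ``chord`` replaces the arc by the 3D chord
    2R·sin(Δθ_wrapped/2).  Accepts scalars (``SurfacePoint``) or arrays
    broadcastable over the last axis ``[z, theta]``.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dz = a[..., 0] - b[..., 0]
    dth = wrapped_angle(a[..., 1] - b[..., 1])
    if metric == "geodesic":
        arc = radius * dth
    elif metric == "chord":
        arc = 2.0 * radius * np.sin(dth / 2.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return np.hypot(dz, arc)


def pairwise_surface_distances(
    points: np.ndarray, radius: float, *, metric: Metric = "geodesic"
) -> np.ndarray:
    """Full ``(n, n)`` surface-distance matrix (zero diagonal)."""
    pts = np.asarray(points, dtype=float)
    return surface_distance(pts[:, None, :], pts[None, :, :], radius, metric=metric)
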