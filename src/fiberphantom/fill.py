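"""Bundle filling and collision detection.

A thick fiber object (the *bundle envelope*) is populated with thin child
fibers.  Seeds are laid out on a triangular lattice in the cross-section of
minimum radius and transported along the trajectory by a moving frame that
is rotated from one data point to the next with the Rodrigues formula.
Where the envelope radius grows, the in-plane offsets are scaled by
``R_j / R_ref`` so inter-fiber distances grow proportionally and, as long
as the seed spacing is at least the fiber diameter, children never
intersect.

Grid convention
---------------
The lattice pitch (``spacing``) is the center-to-center distance between
neighboring child fibers.  The lattice is positioned so that the bundle
axis passes through the centroid of one lattice triangle: the three
innermost fibers are equidistant from the axis and the packing is
maximally symmetric about it.  A seed is kept when its *center* lies inside
the envelope of the reference cross-section (``|seed| ≤ R_ref``).  If no
lattice point fits (spacing larger than the envelope), a single child on
the axis is seeded instead so a fill always produces at least one fiber.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .model import Fiber, FiberGroup, Phantom, rodrigues_rotate

__all__ = [
    "GridSeed",
    "MovingFrame",
    "Collision",
    "triangular_seed_grid",
    "transport_frames",
    "fill_bundle",
    "detect_collisions",
    "segment_pair_distance",
]


@dataclass(frozen=True)
class GridSeed:
    """In-plane offset (µm) of a child fiber at the reference cross-section."""

    u: float
    v: float


@dataclass(frozen=True)
class MovingFrame:
    """Local orthonormal frame at one data point of a bundle trajectory."""

    origin: np.ndarray
    tangent: np.ndarray
    normal_u: np.ndarray
    normal_v: np.ndarray


def triangular_seed_grid(
    R_ref: float, r_fiber: float, spacing: float
) -> list[GridSeed]:
    """Seed positions on a triangular lattice inside a disc of radius ``R_ref``.

    See the module docstring for the lattice convention.  Nearest-neighbor
    center distance equals ``spacing``; every returned pair of seeds is at
    least ``spacing`` apart.
    """
    if R_ref <= 0 or r_fiber <= 0 or spacing <= 0:
        raise ValidationError(
            f"R_ref, r_fiber and spacing must be positive "
            f"(got {R_ref}, {r_fiber}, {spacing})"
        )
    if r_fiber > R_ref:
        raise ValidationError(
            f"fiber radius {r_fiber} exceeds envelope radius {R_ref}: no interior"
        )
    s = float(spacing)
    # lattice basis: rows s*sqrt(3)/2 apart, odd rows shifted s/2; shifting
    # everything by the triangle centroid (s/2, s*sqrt(3)/6) puts a cell
    # center on the axis
    cx, cy = 0.5 * s, s * np.sqrt(3.0) / 6.0
    nmax = int(R_ref / s) + 3
    seeds: list[GridSeed] = []
    limit = R_ref * R_ref * (1.0 + 1e-12) + 1e-12 * s * s
    for j in range(-nmax, nmax + 1):
        v = j * s * np.sqrt(3.0) / 2.0 + cy
        for i in range(-nmax - 1, nmax + 2):
            u = (i + 0.5 * (j % 2)) * s + cx
            if u * u + v * v <= limit:
                seeds.append(GridSeed(u, v))
    if not seeds:
        return [GridSeed(0.0, 0.0)]
    seeds.sort(key=lambda p: (p.u * p.u + p.v * p.v, np.arctan2(p.v, p.u)))
    return seeds


def _initial_normal(tangent: np.ndarray) -> np.ndarray:
    # global axis least aligned with the tangent, projected and normalized;
    # deterministic so repeated fills are reproducible
    k = int(np.argmin(np.abs(tangent)))
    e = np.zeros(3)
    e[k] = 1.0
    n = e - tangent * (e @ tangent)
    return n / np.linalg.norm(n)


def _tangents(xyz: np.ndarray) -> np.ndarray:
    t = np.empty_like(xyz)
    t[0] = xyz[1] - xyz[0]
    t[-1] = xyz[-1] - xyz[-2]
    if xyz.shape[0] > 2:
        t[1:-1] = xyz[2:] - xyz[:-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    return t / norms


def transport_frames(
    parent: Fiber, initial_normal: np.ndarray | None = None
) -> list[MovingFrame]:
    """One orthonormal frame per data point, rotation-transported along the fiber.

    Frame ``i+1`` is frame ``i`` rotated about ``t_i × t_{i+1}`` by the angle
    between the tangents (Rodrigues formula); tangents are normalized central
    differences (one-sided at the ends).  Near-parallel consecutive tangents
    get the identity rotation; antiparallel ones (angle ≈ π) have no unique
    rotation axis — an arbitrary perpendicular axis is used and a warning is
    emitted.
    """
    xyz = parent.xyz
    tangents = _tangents(xyz)
    if initial_normal is None:
        nu = _initial_normal(tangents[0])
    else:
        nu = np.asarray(initial_normal, dtype=float)
        nu = nu - tangents[0] * (nu @ tangents[0])
        norm = np.linalg.norm(nu)
        if norm < 1e-12:
            raise ValidationError("initial normal is parallel to the first tangent")
        nu = nu / norm
    nv = np.cross(tangents[0], nu)
    frames = [MovingFrame(xyz[0].copy(), tangents[0].copy(), nu, nv)]
    for i in range(1, xyz.shape[0]):
        t0, t1 = tangents[i - 1], tangents[i]
        axis = np.cross(t0, t1)
        norm = np.linalg.norm(axis)
        dot = float(np.clip(t0 @ t1, -1.0, 1.0))
        if norm < 1e-12:
            if dot < 0.0:
                warnings.warn(
                    "antiparallel consecutive tangents: rotation axis is "
                    "degenerate, using an arbitrary perpendicular axis",
                    stacklevel=2,
                )
                axis = _initial_normal(t0)
                angle = np.pi
            else:
                axis = None
                angle = 0.0
        else:
            axis = axis / norm
            angle = np.arccos(dot)
        if axis is None or angle == 0.0:
            nu, nv = frames[-1].normal_u, frames[-1].normal_v
        else:
            nu = rodrigues_rotate(frames[-1].normal_u, axis, angle)
            nv = rodrigues_rotate(frames[-1].normal_v, axis, angle)
        frames.append(MovingFrame(xyz[i].copy(), t1.copy(), nu, nv))
    return frames


def reference_radius(parent: Fiber) -> float:
    """Radius of the reference cross-section: the minimum *positive* radius.

    Zero radii (closed fiber tips) are excluded — with them the fill would
    degenerate to the axis.
    """
    radii = parent.radii
    positive = radii[radii > 0.0]
    if positive.size == 0:
        raise ValidationError("bundle envelope has no positive radius anywhere")
    return float(positive.min())


def fill_bundle(
    parent: Fiber,
    r_fiber: float,
    spacing: float,
    initial_normal: np.ndarray | None = None,
) -> FiberGroup:
    """Fill a bundle envelope with child fibers on a triangular grid.

    ``spacing`` is the center-to-center seed distance at the reference
    cross-section (the one of minimum positive radius, see
    :func:`reference_radius`).  At data point ``j`` the in-plane offsets are
    scaled by ``R_j / R_ref``, so spacings grow with the envelope.  All
    children have constant radius ``r_fiber`` and one point per parent data
    point; they are returned as a group named after the parent.
    """
    if spacing < 2.0 * r_fiber:
        warnings.warn(
            f"seed spacing {spacing} is below the fiber diameter "
            f"{2.0 * r_fiber}: children may intersect",
            stacklevel=2,
        )
    R_ref = reference_radius(parent)
    seeds = triangular_seed_grid(R_ref, r_fiber, spacing)
    frames = transport_frames(parent, initial_normal)
    scale = parent.radii / R_ref  # (n,)
    origins = parent.xyz  # (n, 3)
    nu = np.stack([f.normal_u for f in frames])  # (n, 3)
    nv = np.stack([f.normal_v for f in frames])
    group = FiberGroup(name=parent.label)
    for k, seed in enumerate(seeds):
        xyz = origins + scale[:, None] * (seed.u * nu + seed.v * nv)
        data = np.column_stack([xyz, np.full(len(parent), r_fiber)])
        group.add(Fiber(data, label=f"{parent.label}_{k}"))
    return group


# ---------------------------------------------------------------------------
# collision detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Collision:
    """A pair of fibers whose tubes overlap, with the closest-approach point."""

    fiber_a: str
    fiber_b: str
    location: tuple[float, float, float]
    distance: float
    threshold: float


def segment_pair_distance(
    p0: np.ndarray, p1: np.ndarray, q0: np.ndarray, q1: np.ndarray
):
    """Minimum distances between all segment pairs of two polylines.

    ``p0, p1``: (m, 3) endpoints of polyline A's segments; ``q0, q1``:
    (n, 3) of B.  Returns ``(dist, s, t)`` with shape (m, n): the closed-form
    clamped closest-approach solution for every pair, ``s``/``t`` being the
    normalized parameters on the A/B segments.
    """
    d1 = (p1 - p0)[:, None, :]  # (m,1,3)
    d2 = (q1 - q0)[None, :, :]  # (1,n,3)
    r = p0[:, None, :] - q0[None, :, :]
    a = np.sum(d1 * d1, axis=-1)
    e = np.sum(d2 * d2, axis=-1)
    f = np.sum(d2 * r, axis=-1)
    c = np.sum(d1 * r, axis=-1)
    b = np.sum(d1 * d2, axis=-1)
    denom = a * e - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0.0, np.clip((b * f - c * e) / denom, 0.0, 1.0), 0.0)
        # recompute t for the clamped s, then re-clamp s
        t = np.where(e > 0.0, (b * s + f) / e, 0.0)
        t_cl = np.clip(t, 0.0, 1.0)
        s = np.where(a > 0.0, np.clip((b * t_cl - c) / a, 0.0, 1.0), 0.0)
        t = t_cl
    pa = p0[:, None, :] + s[..., None] * d1
    pb = q0[None, :, :] + t[..., None] * d2
    dist = np.linalg.norm(pa - pb, axis=-1)
    return dist, s, t


def _fiber_min_distance(fa: Fiber, fb: Fiber):
    """Closest approach between the axes of two fibers.

    Returns ``(dist, location, threshold)`` where ``threshold`` is
    ``r_a + r_b`` with the radii linearly interpolated at the closest points.
    """
    pa, pb = fa.xyz, fb.xyz
    dist, s, t = segment_pair_distance(pa[:-1], pa[1:], pb[:-1], pb[1:])
    # maximize penetration: minimize dist - (r_a + r_b)
    ra = fa.radii[:-1, None] * (1.0 - s) + fa.radii[1:, None] * s
    rb = fb.radii[None, :-1] * (1.0 - t) + fb.radii[None, 1:] * t
    pen = dist - (ra + rb)
    i, j = np.unravel_index(np.argmin(pen), pen.shape)
    loc = 0.5 * (
        pa[i] + s[i, j] * (pa[i + 1] - pa[i]) + pb[j] + t[i, j] * (pb[j + 1] - pb[j])
    )
    return float(dist[i, j]), tuple(float(v) for v in loc), float(ra[i, j] + rb[i, j])


def detect_collisions(phantom: Phantom, tolerance: float = 0.0) -> list[Collision]:
    """Report every unordered fiber pair whose tubes overlap.

    A pair collides when the minimum axis-to-axis distance is less than
    ``r_a + r_b - tolerance`` (radii interpolated along the segments).
    Results are ordered lexicographically by the fiber path ids.  Fiber
    pairs whose padded bounding boxes do not intersect are skipped.
    """
    if tolerance < 0:
        raise ValidationError(f"tolerance must be non-negative, got {tolerance}")
    fibers = sorted(phantom.iter_fibers(), key=lambda kv: kv[0])
    boxes = []
    for _, f in fibers:
        pad = f.radii.max()
        boxes.append((f.xyz.min(axis=0) - pad, f.xyz.max(axis=0) + pad))
    out: list[Collision] = []
    for i in range(len(fibers)):
        lo_i, hi_i = boxes[i]
        for j in range(i + 1, len(fibers)):
            lo_j, hi_j = boxes[j]
            if np.any(lo_i > hi_j) or np.any(lo_j > hi_i):
                continue
            dist, loc, thresh = _fiber_min_distance(fibers[i][1], fibers[j][1])
            if dist < thresh - tolerance:
                out.append(
                    Collision(fibers[i][0], fibers[j][0], loc, dist, thresh)
                )
    return out
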