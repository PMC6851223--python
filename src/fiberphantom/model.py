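"""Core domain model: fiber objects, groups, phantoms and rigid transforms.

A *fiber object* is an ordered chain of data points, each carrying a 3D
coordinate and a radius (all in µm).  A thin fiber and a thick bundle
envelope are the same kind of object — only the radius differs.  Fibers are
arranged in named, nestable groups; a phantom is the root group holding the
whole model.

Trajectories come from two sources: parametric functions of ``t``
(:func:`eval_parametric`) or cubic-spline interpolation through user control
points (:func:`interpolate_spline`).  Whole fibers or groups can be
translated, rotated, uniformly scaled and duplicated (:func:`transform`).
Rotation uses the Rodrigues axis-angle formula (:func:`rodrigues_rotate`),
which is also the primitive used to transport seeding frames along a bundle
during filling.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator, Sequence, Union

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ValidationError
from .expressions import compile_expression

__all__ = [
    "FiberPoint",
    "Fiber",
    "FiberGroup",
    "Phantom",
    "ParametricDefinition",
    "eval_parametric",
    "interpolate_spline",
    "transform",
    "rodrigues_rotate",
    "rotation_matrix",
]


@dataclass(frozen=True)
class FiberPoint:
    """A single data point of a fiber object: position (µm) and radius (µm)."""

    x: float
    y: float
    z: float
    r: float

    def __post_init__(self) -> None:
        vals = (self.x, self.y, self.z, self.r)
        if not all(np.isfinite(vals)):
            raise ValidationError(f"fiber point has non-finite entries: {vals}")
        if self.r < 0:
            raise ValidationError(f"fiber point has negative radius {self.r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


class Fiber:
    """An ordered chain of ≥ 2 data points.

    Internally the points are a float64 ``(n, 4)`` array with columns
    ``x, y, z, r``; the :class:`FiberPoint` view is constructed on access.
    Consecutive points must be distinct (nonzero segment length).
    """

    def __init__(self, data: np.ndarray | Sequence, label: str = "fiber"):
        arr = np.array(
            [[p.x, p.y, p.z, p.r] for p in data]
            if data is not None and len(data) and isinstance(data[0], FiberPoint)
            else data,
            dtype=float,
        )
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValidationError(f"fiber data must be (n, 4), got {arr.shape}")
        if arr.shape[0] < 2:
            raise ValidationError("a fiber needs at least 2 points")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("fiber data contains non-finite values")
        if np.any(arr[:, 3] < 0):
            raise ValidationError("fiber radii must be non-negative")
        seg = np.linalg.norm(np.diff(arr[:, :3], axis=0), axis=1)
        if np.any(seg == 0.0):
            i = int(np.argmin(seg))
            raise ValidationError(f"consecutive points {i} and {i + 1} are identical")
        self.data = arr
        self.label = str(label)

    # -- array-style access -------------------------------------------------
    @property
    def xyz(self) -> np.ndarray:
        """Coordinates as an ``(n, 3)`` view."""
        return self.data[:, :3]

    @property
    def radii(self) -> np.ndarray:
        return self.data[:, 3]

    @property
    def points(self) -> list[FiberPoint]:
        return [FiberPoint(*row) for row in self.data]

    def __len__(self) -> int:
        return self.data.shape[0]

    def centroid(self) -> np.ndarray:
        return self.xyz.mean(axis=0)

    def copy(self) -> "Fiber":
        return Fiber(self.data.copy(), self.label)

    def __repr__(self) -> str:
        return f"Fiber({self.label!r}, n={len(self)})"


@dataclass
class FiberGroup:
    """A named collection of fibers and/or nested groups."""

    name: str = "group"
    members: list[Union[Fiber, "FiberGroup"]] = field(default_factory=list)
    visible: bool = True

    def add(self, member: Union[Fiber, "FiberGroup"]) -> None:
        if isinstance(member, FiberGroup):
            # reject cycles: a group may not (transitively) contain itself
            stack = [member]
            while stack:
                g = stack.pop()
                if g is self:
                    raise ValidationError(
                        f"adding group {member.name!r} to {self.name!r} creates a cycle"
                    )
                stack.extend(m for m in g.members if isinstance(m, FiberGroup))
        self.members.append(member)

    def iter_fibers(self, prefix: str = "") -> Iterator[tuple[str, Fiber]]:
        """Yield ``(path, fiber)`` pairs in depth-first document order."""
        base = f"{prefix}/{self.name}" if prefix else self.name
        for i, m in enumerate(self.members):
            if isinstance(m, Fiber):
                yield f"{base}/fiber_{i}", m
            else:
                yield from m.iter_fibers(base)

    def iter_groups(self, prefix: str = "") -> Iterator[tuple[str, "FiberGroup"]]:
        base = f"{prefix}/{self.name}" if prefix else self.name
        yield base, self
        for m in self.members:
            if isinstance(m, FiberGroup):
                yield from m.iter_groups(base)

    def n_fibers(self) -> int:
        return sum(1 for _ in self.iter_fibers())

    def centroid(self) -> np.ndarray:
        pts = [f.xyz for _, f in self.iter_fibers()]
        if not pts:
            raise ValidationError(f"group {self.name!r} contains no fibers")
        stacked = np.concatenate(pts, axis=0)
        return stacked.mean(axis=0)

    def copy(self) -> "FiberGroup":
        return copy.deepcopy(self)


@dataclass
class Phantom:
    """A complete fiber model: the root group holding all content."""

    root: FiberGroup = field(default_factory=lambda: FiberGroup("root"))

    def iter_fibers(self) -> Iterator[tuple[str, Fiber]]:
        return self.root.iter_fibers()

    def n_fibers(self) -> int:
        return self.root.n_fibers()

    def add(self, member: Union[Fiber, FiberGroup]) -> None:
        self.root.add(member)

    def copy(self) -> "Phantom":
        return Phantom(self.root.copy())


@dataclass(frozen=True)
class ParametricDefinition:
    """Textual parametric definition of a fiber: x(t), y(t), z(t), r(t)."""

    expr_x: str
    expr_y: str
    expr_z: str
    expr_r: str
    t_min: float = 0.0
    t_max: float = 1.0
    n_steps: int = 100

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValidationError(
                f"need t_min < t_max, got [{self.t_min}, {self.t_max}]"
            )
        if self.n_steps < 1:
            raise ValidationError(f"n_steps must be positive, got {self.n_steps}")


def eval_parametric(defn: ParametricDefinition, label: str = "parametric") -> Fiber:
    """Sample a parametric definition at ``n_steps + 1`` uniform t values.

    Raises :class:`~fiberphantom.errors.ExpressionError` for malformed
    expressions and :class:`~fiberphantom.errors.ValidationError` when an
    evaluated radius is negative (the message names the offending t).
    """
    fx, fy, fz, fr = (
        compile_expression(e)
        for e in (defn.expr_x, defn.expr_y, defn.expr_z, defn.expr_r)
    )
    t = np.linspace(defn.t_min, defn.t_max, defn.n_steps + 1)
    data = np.column_stack([fx(t), fy(t), fz(t), fr(t)])
    neg = data[:, 3] < 0
    if np.any(neg):
        raise ValidationError(
            f"radius expression {defn.expr_r!r} is negative at t={t[neg][0]:g}"
        )
    return Fiber(data, label)


def interpolate_spline(
    controls: Sequence[FiberPoint] | np.ndarray,
    samples_per_segment: int = 10,
    *,
    bc_type: str = "natural",
    parameterization: str = "index",
    label: str = "spline",
) -> Fiber:
    """Cubic-spline interpolate control points (coordinates *and* radii).

    The spline passes exactly through every control point.  By default the
    spline parameter is the control-point index (uniform parameterization)
    with natural boundary conditions; ``parameterization="chord"`` uses
    cumulative chord length, and any ``bc_type`` accepted by
    :class:`scipy.interpolate.CubicSpline` (e.g. ``"not-a-knot"``, which
    reproduces cubic polynomials exactly) can be requested.

    Output point count is ``(n_controls - 1) * samples_per_segment + 1``.
    """
    ctrl = np.asarray(
        [[p.x, p.y, p.z, p.r] for p in controls]
        if len(controls) and isinstance(controls[0], FiberPoint)
        else controls,
        dtype=float,
    )
    if ctrl.ndim != 2 or ctrl.shape[1] != 4:
        raise ValidationError(f"controls must be (n, 4), got {ctrl.shape}")
    if ctrl.shape[0] < 2:
        raise ValidationError("spline interpolation needs at least 2 control points")
    if samples_per_segment < 1:
        raise ValidationError("samples_per_segment must be positive")
    dseg = np.linalg.norm(np.diff(ctrl[:, :3], axis=0), axis=1)
    if np.any(dseg == 0.0):
        i = int(np.argmin(dseg))
        raise ValidationError(f"duplicated consecutive control points {i}, {i + 1}")

    n = ctrl.shape[0]
    if parameterization == "index":
        s = np.arange(n, dtype=float)
    elif parameterization == "chord":
        s = np.concatenate([[0.0], np.cumsum(dseg)])
    else:
        raise ValidationError(f"unknown parameterization {parameterization!r}")

    if n == 2:
        # a cubic through two points is underdetermined; use the segment
        u = np.linspace(s[0], s[-1], samples_per_segment + 1)
        w = (u - s[0]) / (s[-1] - s[0])
        data = ctrl[0] + np.outer(w, ctrl[1] - ctrl[0])
        return Fiber(data, label)

    spline = CubicSpline(s, ctrl, axis=0, bc_type=bc_type)
    # sample uniformly within each inter-control segment so every control
    # point is an output node
    u = np.concatenate(
        [
            np.linspace(s[i], s[i + 1], samples_per_segment, endpoint=False)
            for i in range(n - 1)
        ]
        + [s[-1:]]
    )
    data = spline(u)
    data[:, 3] = np.maximum(data[:, 3], 0.0)  # spline overshoot may dip below 0
    return Fiber(data, label)


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """3×3 rotation matrix for a unit axis and an angle in radians."""
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValidationError(f"rotation axis must be unit length, |a|={np.linalg.norm(axis)}")
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def rodrigues_rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate vector(s) ``v`` about a unit ``axis`` by ``angle`` radians.

    Implements v cosθ + (a × v) sinθ + a (a·v)(1 − cosθ).  ``v`` may be a
    single 3-vector or an ``(n, 3)`` array.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if abs(norm - 1.0) > 1e-9:
        raise ValidationError(f"rotation axis must be unit length, |a|={norm}")
    v = np.asarray(v, dtype=float)
    c, s = np.cos(angle), np.sin(angle)
    cross = np.cross(np.broadcast_to(axis, v.shape), v)
    dot = v @ axis
    return v * c + cross * s + np.multiply.outer(dot, axis) * (1.0 - c)


def _apply_pointwise(target: Fiber | FiberGroup, fn) -> None:
    if isinstance(target, Fiber):
        target.data = fn(target.data)
    else:
        for m in target.members:
            _apply_pointwise(m, fn)


def transform(
    target: Fiber | FiberGroup,
    kind: str,
    *,
    offset: Sequence[float] | None = None,
    axis: Sequence[float] | None = None,
    angle: float | None = None,
    pivot: Sequence[float] | None = None,
    factor: float | None = None,
    in_place: bool = False,
) -> Fiber | FiberGroup:
    """Apply a rigid transform or duplication to a fiber or group.

    kind
        ``"translate"`` (needs ``offset``), ``"rotate"`` (needs unit
        ``axis`` and ``angle`` in radians; ``pivot`` defaults to the target
        centroid), ``"scale"`` (uniform positive ``factor`` applied to
        coordinates *and* radii about ``pivot``, default centroid), or
        ``"duplicate"`` (deep copy; the original is untouched).

    Group transforms recurse into all members.  By default a transformed
    copy is returned; pass ``in_place=True`` to modify ``target`` itself.
    """
    if kind == "duplicate":
        return target.copy()
    out = target if in_place else target.copy()

    if kind == "translate":
        if offset is None:
            raise ValidationError("translate requires an offset")
        d = np.asarray(offset, dtype=float)

        def fn(data):
            data = data.copy()
            data[:, :3] += d
            return data

    elif kind == "rotate":
        if axis is None or angle is None:
            raise ValidationError("rotate requires axis and angle")
        a = np.asarray(axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0.0:
            raise ValidationError("rotation axis must not be the zero vector")
        if abs(n - 1.0) > 1e-9:
            raise ValidationError(f"rotation axis must be unit length, |a|={n}")
        p = np.asarray(pivot, dtype=float) if pivot is not None else out.centroid()

        def fn(data):
            data = data.copy()
            data[:, :3] = rodrigues_rotate(data[:, :3] - p, a, angle) + p
            return data

    elif kind == "scale":
        if factor is None or factor <= 0:
            raise ValidationError(f"scale requires a positive factor, got {factor}")
        p = np.asarray(pivot, dtype=float) if pivot is not None else out.centroid()

        def fn(data):
            data = data.copy()
            data[:, :3] = (data[:, :3] - p) * factor + p
            data[:, 3] *= factor
            return data

    else:
        raise ValidationError(f"unknown transform kind {kind!r}")

    _apply_pointwise(out, fn)
    return out
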