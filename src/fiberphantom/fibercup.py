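"""Programmatic construction of the Fiber Cup phantom.

The Fiber Cup is a standard benchmark layout for fiber-reconstruction
methods: seven fiber bundles arranged on a circular plate with crossing,
fanning and bending configurations.  Here each bundle's center line is
encoded as a small table of spline control points (a versioned fixture of
this package, reproducing the layout's topology rather than any particular
hardware phantom's exact geometry): one straight transverse bundle (3),
three bundles (4, 5, 6) that merge into one corridor and cross the
transverse bundle, a long bending bundle (1), a diagonal bundle (2)
crossing the transverse one, and a bending bundle in the lower half (7).

Defaults follow the scale at which such phantoms are simulated for
polarized-light imaging: bundle diameter 120 µm, child fiber diameter
1.5 µm with a 1.5 µm surface gap (center spacing 3 µm), 42 sample points
per fiber.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ValidationError
from .fill import fill_bundle
from .model import Fiber, FiberGroup, Phantom

__all__ = [
    "FiberCupConfig",
    "default_config",
    "build_fibercup",
    "fill_fibercup",
    "save_config",
    "load_config",
]

# control points (x, y) in µm on the mid-plane z = 0 of a plate of diameter
# 2000 µm; bundles 4-6 share their tail so they merge into one corridor
_DEFAULT_BUNDLES: list[tuple[str, list[tuple[float, float]]]] = [
    ("bundle_1", [(-450.0, 820.0), (-750.0, 500.0), (-900.0, 0.0),
                  (-750.0, -500.0), (-450.0, -820.0)]),
    ("bundle_2", [(-350.0, -850.0), (-260.0, -420.0), (-250.0, 0.0),
                  (-240.0, 420.0), (-150.0, 850.0)]),
    ("bundle_3", [(-950.0, 0.0), (-475.0, 0.0), (0.0, 0.0),
                  (475.0, 0.0), (950.0, 0.0)]),
    ("bundle_4", [(950.0, -150.0), (600.0, -50.0),
                  (200.0, 50.0), (-200.0, 350.0), (-600.0, 720.0)]),
    ("bundle_5", [(850.0, -450.0), (500.0, -150.0),
                  (200.0, 50.0), (-200.0, 350.0), (-600.0, 720.0)]),
    ("bundle_6", [(700.0, -650.0), (420.0, -300.0),
                  (200.0, 50.0), (-200.0, 350.0), (-600.0, 720.0)]),
    ("bundle_7", [(900.0, -350.0), (600.0, -550.0), (350.0, -700.0),
                  (100.0, -820.0), (-100.0, -930.0)]),
]


@dataclass(frozen=True)
class FiberCupConfig:
    """Geometry and fill parameters of the Fiber Cup phantom (lengths in µm)."""

    bundle_diameter: float = 120.0
    fiber_diameter: float = 1.5
    fiber_gap: float = 1.5
    plate_diameter: float = 2000.0
    samples_per_fiber: int = 42
    bundles: tuple[tuple[str, tuple[tuple[float, float], ...]], ...] = field(
        default_factory=lambda: tuple(
            (name, tuple(pts)) for name, pts in _DEFAULT_BUNDLES
        )
    )

    def __post_init__(self) -> None:
        for value, name in [
            (self.bundle_diameter, "bundle_diameter"),
            (self.fiber_diameter, "fiber_diameter"),
            (self.fiber_gap, "fiber_gap"),
            (self.plate_diameter, "plate_diameter"),
        ]:
            if value <= 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        if self.samples_per_fiber < 2:
            raise ValidationError("samples_per_fiber must be at least 2")
        if len(self.bundles) != 7:
            raise ValidationError(
                f"the Fiber Cup has exactly 7 bundles, got {len(self.bundles)}"
            )

    @property
    def fiber_spacing(self) -> float:
        """Center-to-center seed spacing: fiber diameter plus surface gap."""
        return self.fiber_diameter + self.fiber_gap

    def scaled(self, factor: float) -> "FiberCupConfig":
        """A geometrically similar config with all lengths scaled by ``factor``."""
        if factor <= 0:
            raise ValidationError(f"scale factor must be positive, got {factor}")
        return replace(
            self,
            bundle_diameter=self.bundle_diameter * factor,
            fiber_diameter=self.fiber_diameter * factor,
            fiber_gap=self.fiber_gap * factor,
            plate_diameter=self.plate_diameter * factor,
            bundles=tuple(
                (name, tuple((x * factor, y * factor) for x, y in pts))
                for name, pts in self.bundles
            ),
        )


def default_config() -> FiberCupConfig:
    return FiberCupConfig()


def _sample_bundle(
    controls: np.ndarray, radius: float, n_samples: int, label: str
) -> Fiber:
    """Natural cubic spline through the control points, ``n_samples`` points."""
    s = np.arange(controls.shape[0], dtype=float)
    spline = CubicSpline(s, controls, axis=0, bc_type="natural")
    u = np.linspace(s[0], s[-1], n_samples)
    xy = spline(u)
    data = np.column_stack(
        [xy[:, 0], xy[:, 1], np.zeros(n_samples), np.full(n_samples, radius)]
    )
    return Fiber(data, label=label)


def build_fibercup(config: FiberCupConfig | None = None) -> Phantom:
    """Build the seven bundle envelopes (unfilled) as a phantom."""
    config = config or default_config()
    root = FiberGroup("fibercup")
    radius = config.bundle_diameter / 2.0
    for name, pts in config.bundles:
        controls = np.asarray(pts, dtype=float)
        root.add(
            _sample_bundle(controls, radius, config.samples_per_fiber, name)
        )
    return Phantom(root)


def fill_fibercup(
    phantom: Phantom, config: FiberCupConfig | None = None
) -> Phantom:
    """Fill every bundle envelope with thin fibers on the triangular grid.

    Overlapping envelopes are filled independently, so crossing and merge
    regions get a correspondingly multiplied local fiber density.
    """
    config = config or default_config()
    root = FiberGroup("fibercup_filled")
    r_fiber = config.fiber_diameter / 2.0
    for _, envelope in phantom.iter_fibers():
        root.add(fill_bundle(envelope, r_fiber, config.fiber_spacing))
    return Phantom(root)


# ---------------------------------------------------------------------------
# structured text config
# ---------------------------------------------------------------------------


def save_config(config: FiberCupConfig, path: str) -> None:
    """Write a config as key-value lines plus per-bundle control tables."""
    lines = [
        f"bundle_diameter = {config.bundle_diameter:g}",
        f"fiber_diameter = {config.fiber_diameter:g}",
        f"fiber_gap = {config.fiber_gap:g}",
        f"plate_diameter = {config.plate_diameter:g}",
        f"samples_per_fiber = {config.samples_per_fiber}",
    ]
    for name, pts in config.bundles:
        lines.append(f"[bundle {name}]")
        lines.extend(f"{x:g} {y:g}" for x, y in pts)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_config(path: str) -> FiberCupConfig:
    """Read a config written by :func:`save_config`."""
    scalars: dict[str, float] = {}
    bundles: list[tuple[str, list[tuple[float, float]]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[bundle ") and line.endswith("]"):
                bundles.append((line[len("[bundle "):-1].strip(), []))
            elif "=" in line:
                key, _, value = line.partition("=")
                scalars[key.strip()] = float(value)
            else:
                if not bundles:
                    raise ValidationError(
                        f"{path}:{lineno}: control point outside a bundle section"
                    )
                fields = line.split()
                if len(fields) != 2:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 'x y', got {line!r}"
                    )
                bundles[-1][1].append((float(fields[0]), float(fields[1])))
    kwargs: dict = {k: scalars[k] for k in (
        "bundle_diameter", "fiber_diameter", "fiber_gap", "plate_diameter"
    ) if k in scalars}
    if "samples_per_fiber" in scalars:
        kwargs["samples_per_fiber"] = int(scalars["samples_per_fiber"])
    if bundles:
        kwargs["bundles"] = tuple((n, tuple(p)) for n, p in bundles)
    return FiberCupConfig(**kwargs)
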