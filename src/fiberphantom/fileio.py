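"""Phantom serialization: HDF5 dialect and plain-text format.

Coordinates and radii are stored in single precision (float32) in both
formats, matching the storage resolution of the fiber data points; a
write/read round trip reproduces every value after float32 quantization.

HDF5 layout (format_version "1")
--------------------------------
The file root carries attributes ``format_version``, ``units`` ("um") and
the root group's ``name``.  Every nested fiber group becomes an HDF5 group
(attribute ``visible``); every fiber a 2D float32 dataset ``fiber_<index>``
with columns x, y, z, r and a ``label`` attribute.  Sibling order is kept
in a ``member_order`` attribute.

Text dialect
------------
``# group: <slash-separated path>`` lines open a group; each fiber is a
block of ``x y z r`` lines (9 significant digits, lossless for float32)
separated by blank lines.
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from .errors import FormatError, ValidationError
from .model import Fiber, FiberGroup, Phantom

__all__ = [
    "write_hdf5",
    "read_hdf5",
    "write_text",
    "read_text",
    "write_volume",
    "read_volume",
    "write_stack",
    "read_stack",
    "write_orientation_map",
    "read_orientation_map",
    "FORMAT_VERSION",
]

FORMAT_VERSION = "1"


def _check_nonempty(phantom: Phantom) -> None:
    if phantom.n_fibers() == 0:
        raise ValidationError("refusing to write an empty phantom (no fibers)")


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------


def _write_group(h5grp: h5py.Group, group: FiberGroup) -> None:
    h5grp.attrs["name"] = group.name
    h5grp.attrs["visible"] = bool(group.visible)
    order = []
    used: set[str] = set()
    for i, m in enumerate(group.members):
        if isinstance(m, Fiber):
            key = f"fiber_{i}"
            ds = h5grp.create_dataset(key, data=m.data.astype(np.float32))
            ds.attrs["label"] = m.label
        else:
            key = m.name if m.name not in used else f"{m.name}_{i}"
            used.add(key)
            _write_group(h5grp.create_group(key), m)
        order.append(key)
    h5grp.attrs["member_order"] = np.array(order, dtype=h5py.string_dtype())


def _read_group(h5grp: h5py.Group) -> FiberGroup:
    name = h5grp.attrs.get("name", os.path.basename(h5grp.name) or "root")
    group = FiberGroup(str(name), visible=bool(h5grp.attrs.get("visible", True)))
    order = [
        k.decode() if isinstance(k, bytes) else str(k)
        for k in h5grp.attrs.get("member_order", list(h5grp.keys()))
    ]
    for key in order:
        node = h5grp[key]
        if isinstance(node, h5py.Dataset):
            group.add(Fiber(np.asarray(node, dtype=float),
                            label=str(node.attrs.get("label", key))))
        else:
            group.add(_read_group(node))
    return group


def write_hdf5(phantom: Phantom, path: str | os.PathLike) -> None:
    """Write a phantom to the package's HDF5 dialect (single precision)."""
    _check_nonempty(phantom)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["units"] = "um"
        _write_group(f, phantom.root)


def read_hdf5(path: str | os.PathLike) -> Phantom:
    """Read a phantom written by :func:`write_hdf5`."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"cannot open {path} as HDF5: {exc}") from exc
    with f:
        version = f.attrs.get("format_version")
        if version is None:
            raise FormatError(f"{path}: missing format_version attribute")
        if str(version) != FORMAT_VERSION:
            raise FormatError(
                f"{path}: unsupported format version {version!r} "
                f"(this reader supports {FORMAT_VERSION!r})"
            )
        return Phantom(_read_group(f))


# ---------------------------------------------------------------------------
# plain text
# ---------------------------------------------------------------------------


def write_text(phantom: Phantom, path: str | os.PathLike) -> None:
    """Write a phantom to the plain-text dialect (single precision)."""
    _check_nonempty(phantom)
    lines: list[str] = []

    def emit(group: FiberGroup, prefix: str) -> None:
        gpath = f"{prefix}/{group.name}" if prefix else group.name
        lines.append(f"# group: {gpath}")
        for m in group.members:
            if isinstance(m, Fiber):
                data = m.data.astype(np.float32)
                for row in data:
                    lines.append(" ".join(f"{v:.9g}" for v in row))
                lines.append("")
            else:
                emit(m, gpath)
                # reopen the parent so following fibers attach to it on read
                lines.append(f"# group: {gpath}")

    emit(phantom.root, "")
    with open(path, "w") as fh:
        fh.write("\n".join(lines).rstrip("\n") + "\n")


def read_text(path: str | os.PathLike) -> Phantom:
    """Read a phantom written by :func:`write_text`."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    with open(path) as fh:
        raw = fh.read().splitlines()

    groups: dict[str, FiberGroup] = {}
    root: FiberGroup | None = None

    def get_group(gpath: str) -> FiberGroup:
        nonlocal root
        if gpath in groups:
            return groups[gpath]
        parts = gpath.split("/")
        g = FiberGroup(parts[-1])
        groups[gpath] = g
        if len(parts) == 1:
            if root is not None:
                raise FormatError(f"{path}: multiple root groups")
            root = g
        else:
            get_group("/".join(parts[:-1])).add(g)
        return g

    current: FiberGroup | None = None
    block: list[list[float]] = []
    block_start = 0

    def flush() -> None:
        nonlocal block
        if not block:
            return
        if current is None:
            raise FormatError(f"{path}:{block_start}: fiber data before any group")
        if len(block) < 2:
            raise ValidationError(
                f"{path}:{block_start}: fiber with fewer than 2 points"
            )
        # storage is single precision: parse through float32 so a decimal
        # written with 9 significant digits recovers the exact stored value
        current.add(Fiber(np.array(block, dtype=np.float32).astype(float),
                          label=f"fiber_{len(current.members)}"))
        block = []

    for lineno, line in enumerate(raw, start=1):
        stripped = line.strip()
        if stripped.startswith("# group:"):
            flush()
            current = get_group(stripped[len("# group:"):].strip())
        elif stripped.startswith("#"):
            continue
        elif not stripped:
            flush()
        else:
            fields = stripped.split()
            if len(fields) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 columns 'x y z r', "
                    f"got {len(fields)}"
                )
            try:
                values = [float(v) for v in fields]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if not block:
                block_start = lineno
            block.append(values)
    flush()
    if root is None:
        raise FormatError(f"{path}: no group header found")
    return Phantom(root)


# ---------------------------------------------------------------------------
# simulation artifacts (voxel volumes, image stacks, orientation maps)
# ---------------------------------------------------------------------------


def write_volume(volume, path: str | os.PathLike) -> None:
    """Write a voxelized orientation volume as an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["content"] = "voxel_volume"
        f.attrs["voxel_size_um"] = float(volume.voxel_size)
        f.attrs["origin_um"] = np.asarray(volume.origin, dtype=float)
        f.create_dataset("orientation", data=volume.orientation.astype(np.float32))
        f.create_dataset("tissue", data=volume.tissue.astype(np.uint8))


def read_volume(path: str | os.PathLike):
    from .pli import VoxelVolume

    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        return VoxelVolume(
            orientation=np.asarray(f["orientation"], dtype=float),
            tissue=np.asarray(f["tissue"]).astype(bool),
            voxel_size=float(f.attrs["voxel_size_um"]),
            origin=np.asarray(f.attrs["origin_um"], dtype=float),
        )


def write_stack(
    stack: np.ndarray,
    params,
    path: str | os.PathLike,
    *,
    voxel_size: float | None = None,
    noise_seed: int | None = None,
) -> None:
    """Write a simulated image stack with its measurement metadata."""
    import json

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["content"] = "image_stack"
        f.attrs["optics_params"] = json.dumps(params.to_dict())
        f.attrs["rotation_angles_rad"] = np.asarray(params.rotation_angles)
        if voxel_size is not None:
            f.attrs["voxel_size_um"] = float(voxel_size)
        if noise_seed is not None:
            f.attrs["noise_seed"] = int(noise_seed)
        f.create_dataset("images", data=stack.astype(np.float32))


def read_stack(path: str | os.PathLike):
    """Read an image stack; returns ``(stack, params, attrs)``."""
    import json

    from .pli import OpticsParams

    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        stack = np.asarray(f["images"], dtype=float)
        params = OpticsParams.from_dict(json.loads(f.attrs["optics_params"]))
        attrs = {
            k: f.attrs[k]
            for k in ("voxel_size_um", "noise_seed")
            if k in f.attrs
        }
    return stack, params, attrs


def write_orientation_map(fom, path: str | os.PathLike) -> None:
    """Write a recovered orientation map (φ, α, validity mask) as HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["content"] = "orientation_map"
        f.create_dataset("direction", data=fom.direction.astype(np.float32))
        f.create_dataset("inclination", data=fom.inclination.astype(np.float32))
        f.create_dataset("mask", data=fom.mask.astype(np.uint8))


def read_orientation_map(path: str | os.PathLike):
    from .pli import OrientationMap

    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        return OrientationMap(
            direction=np.asarray(f["direction"], dtype=float),
            inclination=np.asarray(f["inclination"], dtype=float),
            mask=np.asarray(f["mask"]).astype(bool),
        )
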