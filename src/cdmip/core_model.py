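"""Domain types, coordinate conventions and file IO.

Conventions used throughout the package:

* Volumes are indexed ``[z][y][x]``; CDM images ``[y][x]``; origin top-left,
  x increases rightward.  The mirror axis is x.
* Physical coordinates are micrometres (µm) in a shared alignment space.
  A µm coordinate maps to a voxel index by ``floor(coord / voxel_size)``,
  so voxel ``i`` covers the half-open interval ``[i*vs, (i+1)*vs)`` and its
  reference point is ``i*vs``.  Converting µm -> voxel -> µm therefore loses
  at most one voxel per axis.
* Intensities are unsigned integers with a declared bit depth (8 or 12).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import tifffile
import yaml
from PIL import Image

__all__ = [
    "AlignmentSpace",
    "Volume3D",
    "Skeleton",
    "SkeletonNode",
    "CDMImage",
    "VoxelSet",
    "ShapeDescriptor",
    "SwcParseError",
    "SwcStructureError",
    "DimensionError",
    "FormatError",
    "read_swc",
    "write_swc",
    "read_stack",
    "write_stack",
    "read_cdm_png",
    "write_cdm_png",
    "read_space_config",
    "write_space_config",
]


class SwcParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class SwcStructureError(ValueError):
    """An SWC file parsed but violates skeleton invariants."""


class DimensionError(ValueError):
    """An image or volume does not have the shape its alignment space declares."""


class FormatError(ValueError):
    """A file is not in the expected pixel format."""


@dataclass(frozen=True)
class AlignmentSpace:
    """A shared registration template: grid shape, voxel size and midline.

    Parameters
    ----------
    name : str
        Identifier of the template (e.g. a unisex brain template name).
    shape_xyz : (int, int, int)
        Grid extent in voxels along x, y, z.
    voxel_size_um : (float, float, float)
        Physical voxel size in µm along x, y, z.
    midline_x_um : float, optional
        x position of the sagittal midline in µm.  Defaults to half the
        physical width, which is correct for symmetric templates.
    """

    name: str
    shape_xyz: tuple[int, int, int]
    voxel_size_um: tuple[float, float, float]
    midline_x_um: float | None = None

    def __post_init__(self) -> None:
        sx, sy, sz = self.shape_xyz
        if min(sx, sy, sz) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.shape_xyz}")
        if min(self.voxel_size_um) <= 0:
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size_um}")
        object.__setattr__(self, "shape_xyz", (int(sx), int(sy), int(sz)))
        object.__setattr__(
            self, "voxel_size_um", tuple(float(v) for v in self.voxel_size_um)
        )
        if self.midline_x_um is None:
            object.__setattr__(self, "midline_x_um", self.width_um / 2.0)
        if not 0.0 <= self.midline_x_um <= self.width_um:
            raise ValueError(
                f"midline {self.midline_x_um} outside [0, {self.width_um}] µm"
            )

    @property
    def width_um(self) -> float:
        return self.shape_xyz[0] * self.voxel_size_um[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        sx, sy, sz = self.shape_xyz
        return (sz, sy, sx)

    def um_to_voxel(self, xyz_um: Sequence[float]) -> tuple[int, int, int]:
        """Map a physical µm coordinate to its (x, y, z) voxel index."""
        return tuple(
            int(np.floor(c / v)) for c, v in zip(xyz_um, self.voxel_size_um)
        )

    def contains_voxel(self, x: int, y: int, z: int) -> bool:
        sx, sy, sz = self.shape_xyz
        return 0 <= x < sx and 0 <= y < sy and 0 <= z < sz


def _max_intensity(bit_depth: int) -> int:
    if bit_depth not in (8, 12):
        raise ValueError(f"bit depth must be 8 or 12, got {bit_depth}")
    return (1 << bit_depth) - 1


@dataclass
class Volume3D:
    """A 3D grayscale intensity grid in an alignment space, indexed [z][y][x]."""

    space: AlignmentSpace
    data: np.ndarray
    bit_depth: int = 8
    channel_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.space.shape_zyx:
            raise DimensionError(
                f"volume shape {self.data.shape} != space shape "
                f"{self.space.shape_zyx} (z, y, x)"
            )
        mx = _max_intensity(self.bit_depth)
        if self.data.size and (self.data.min() < 0 or self.data.max() > mx):
            raise ValueError(f"intensities outside [0, {mx}] for {self.bit_depth}-bit")

    @property
    def max_intensity(self) -> int:
        return _max_intensity(self.bit_depth)


@dataclass(frozen=True)
class SkeletonNode:
    node_id: int
    node_type: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int


@dataclass
class Skeleton:
    """An SWC-style node forest with µm coordinates in an alignment space."""

    nodes: list[SkeletonNode]
    space: AlignmentSpace

    def __post_init__(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise SwcStructureError("duplicate node ids")
        id_set = set(ids)
        g = nx.DiGraph()
        g.add_nodes_from(ids)
        for n in self.nodes:
            if n.parent_id != -1:
                if n.parent_id not in id_set:
                    raise SwcStructureError(
                        f"node {n.node_id} has dangling parent {n.parent_id}"
                    )
                g.add_edge(n.parent_id, n.node_id)
        if not nx.is_directed_acyclic_graph(g):
            raise SwcStructureError("skeleton graph contains a cycle")

    def __len__(self) -> int:
        return len(self.nodes)

    def edges(self) -> Iterator[tuple[SkeletonNode, SkeletonNode]]:
        """Yield (parent, child) node pairs."""
        by_id = {n.node_id: n for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                yield by_id[n.parent_id], n

    def coords_um(self) -> np.ndarray:
        """(N, 3) array of node x, y, z positions in µm."""
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)


@dataclass
class CDMImage:
    """A color depth MIP: RGB [y][x] image where color encodes depth (z).

    Black (0, 0, 0) pixels are background; any non-black pixel's color
    decodes to a z slice index through a :class:`~cdmip.cdm_encoding.DepthLUT`.
    """

    space: AlignmentSpace
    pixels: np.ndarray
    source_id: str = ""
    variant: str = "original"

    VARIANTS = ("original", "flipped", "combined")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        sx, sy, _ = self.space.shape_xyz
        if self.pixels.shape != (sy, sx, 3):
            raise DimensionError(
                f"CDM shape {self.pixels.shape} != (y={sy}, x={sx}, 3)"
            )
        if self.variant not in self.VARIANTS:
            raise ValueError(f"variant must be one of {self.VARIANTS}")

    def foreground_mask(self) -> np.ndarray:
        """Boolean [y][x] mask of non-black pixels."""
        return self.pixels.any(axis=2)

    def with_pixels(self, pixels: np.ndarray, variant: str | None = None) -> "CDMImage":
        return CDMImage(
            space=self.space,
            pixels=pixels,
            source_id=self.source_id,
            variant=self.variant if variant is None else variant,
        )


@dataclass(frozen=True)
class ShapeDescriptor:
    """Simple Fiji-style shape statistics of a voxel set."""

    n_voxels: int
    bbox_extent_um: tuple[float, float, float]  # along x, y, z
    elongation: float  # longest / shortest bounding-box edge (>= 1)


@dataclass
class VoxelSet:
    """A connected set of foreground voxels with intensities.

    ``coords`` is an (N, 3) integer array of (x, y, z) voxel indices;
    ``intensities`` the matching (N,) intensity values.
    """

    space: AlignmentSpace
    coords: np.ndarray
    intensities: np.ndarray
    descriptor: ShapeDescriptor = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 3)
        self.intensities = np.asarray(self.intensities).reshape(-1)
        if len(self.coords) < 1:
            raise ValueError("a voxel set must contain at least one voxel")
        if len(self.coords) != len(self.intensities):
            raise ValueError("coords and intensities length mismatch")
        sx, sy, sz = self.space.shape_xyz
        lo = self.coords.min(axis=0)
        hi = self.coords.max(axis=0)
        if lo.min() < 0 or hi[0] >= sx or hi[1] >= sy or hi[2] >= sz:
            raise ValueError("voxel coordinates outside space bounds")
        vs = np.array(self.space.voxel_size_um)
        extent = (hi - lo + 1) * vs
        self.descriptor = ShapeDescriptor(
            n_voxels=len(self.coords),
            bbox_extent_um=tuple(float(e) for e in extent),
            elongation=float(extent.max() / extent.min()),
        )

    def __len__(self) -> int:
        return len(self.coords)


# ---------------------------------------------------------------------------
# SWC IO
# ---------------------------------------------------------------------------

def read_swc(path: str | os.PathLike, space: AlignmentSpace) -> Skeleton:
    """Read a whitespace-delimited 7-column SWC file.

    Blank lines and ``#`` comments are accepted.  Coordinates are taken as µm
    in ``space``.  Raises :class:`SwcParseError` naming the offending line for
    malformed input and :class:`SwcStructureError` for dangling parents,
    duplicate ids or cycles.
    """
    nodes: list[SkeletonNode] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(
                    f"{path}: line {lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nodes.append(
                    SkeletonNode(
                        node_id=int(parts[0]),
                        node_type=int(parts[1]),
                        x=float(parts[2]),
                        y=float(parts[3]),
                        z=float(parts[4]),
                        radius=float(parts[5]),
                        parent_id=int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SwcParseError(f"{path}: line {lineno}: {exc}") from exc
    return Skeleton(nodes=nodes, space=space)


def write_swc(skeleton: Skeleton, path: str | os.PathLike) -> None:
    """Write a skeleton as standard single-space-delimited SWC text."""
    if not skeleton.nodes:
        raise ValueError("refusing to write an empty skeleton")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# SWC written by cdmip\n")
        for n in skeleton.nodes:
            fh.write(
                f"{n.node_id} {n.node_type} {n.x:g} {n.y:g} {n.z:g} "
                f"{n.radius:g} {n.parent_id}\n"
            )


# ---------------------------------------------------------------------------
# TIFF stack IO
# ---------------------------------------------------------------------------

def read_stack(
    path: str | os.PathLike,
    space: AlignmentSpace,
    bit_depth: int = 8,
    channel_id: str | None = None,
) -> Volume3D:
    """Read a single- or multi-page grayscale TIFF as a [z][y][x] volume."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected grayscale pages, got shape {data.shape}")
    if data.shape != space.shape_zyx:
        raise DimensionError(
            f"{path}: stack shape {data.shape} != space shape {space.shape_zyx}"
        )
    return Volume3D(space=space, data=data, bit_depth=bit_depth, channel_id=channel_id)


def write_stack(vol: Volume3D, path: str | os.PathLike) -> None:
    dtype = np.uint8 if vol.bit_depth == 8 else np.uint16
    tifffile.imwrite(path, vol.data.astype(dtype))


# ---------------------------------------------------------------------------
# CDM PNG IO
# ---------------------------------------------------------------------------

def write_cdm_png(cdm: CDMImage, path: str | os.PathLike) -> None:
    Image.fromarray(cdm.pixels, mode="RGB").save(path, format="PNG")


def read_cdm_png(
    path: str | os.PathLike,
    space: AlignmentSpace,
    source_id: str = "",
    variant: str = "original",
) -> CDMImage:
    """Read an 8-bit RGB PNG as a CDM.  Round trips with :func:`write_cdm_png`
    are bit-exact."""
    img = Image.open(path)
    if img.mode != "RGB":
        raise FormatError(f"{path}: expected 8-bit RGB PNG, got mode {img.mode}")
    pixels = np.asarray(img, dtype=np.uint8)
    return CDMImage(space=space, pixels=pixels, source_id=source_id, variant=variant)


# ---------------------------------------------------------------------------
# Alignment-space config files
# ---------------------------------------------------------------------------

def read_space_config(path: str | os.PathLike) -> AlignmentSpace:
    """Load an alignment space from a YAML/JSON key-value config file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    try:
        return AlignmentSpace(
            name=str(cfg["name"]),
            shape_xyz=tuple(cfg["shape_xyz"]),
            voxel_size_um=tuple(cfg["voxel_size_um"]),
            midline_x_um=cfg.get("midline_x_um"),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing space config key {exc}") from exc


def write_space_config(space: AlignmentSpace, path: str | os.PathLike) -> None:
    cfg = {
        "name": space.name,
        "shape_xyz": list(space.shape_xyz),
        "voxel_size_um": list(space.voxel_size_um),
        "midline_x_um": space.midline_x_um,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
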