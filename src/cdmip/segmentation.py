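"""Direction-selective local thresholding (DSLT) segmentation of LM channels.

Confocal channels carry tissue background haze that defeats a global
threshold.  DSLT-style segmentation compares each voxel against the local
background estimated as the mean intensity along oriented line kernels: a
voxel is foreground when it exceeds that local mean by ``local_offset`` in
enough of the probed directions.  Thin, tube-like neurites stand out in
almost every direction (the kernel line leaves the neurite quickly), while
smooth haze never does.  Connected components of the mask become voxel
sets; small "junk" sets are removed by shape-descriptor thresholds and the
survivors are encoded as per-set CDMs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_model import AlignmentSpace, CDMImage, VoxelSet, Volume3D
from .cdm_encoding import DepthLUT, encode_volume

__all__ = [
    "SegmentationParams",
    "DIRECTIONS_13",
    "dslt_segment",
    "label_components",
    "filter_components",
    "voxelsets_to_cdms",
    "segment_channel",
]

#: The 13 symmetric 3D directions (x, y, z): 3 axes, 6 face diagonals,
#: 4 space diagonals.  Opposite directions are redundant for a symmetric
#: line kernel and are omitted.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, -1, 1), (1, 1, -1), (1, -1, -1),
)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the DSLT pipeline.

    line_kernel_length_um : full physical length of the oriented line kernel.
    n_directions : number of probed orientations (first n of DIRECTIONS_13).
    local_offset : intensity margin a voxel must exceed the local mean by.
    min_directions_hit : directions that must vote foreground.
    min_voxels / shape_thresholds / max_sets_per_channel : junk filtering.
    """

    line_kernel_length_um: float = 10.0
    n_directions: int = 13
    local_offset: float = 15.0
    min_directions_hit: int = 8
    min_voxels: int = 200
    max_sets_per_channel: int = 8
    min_bbox_extent_um: float = 10.0
    max_elongation: float = 1000.0

    def __post_init__(self) -> None:
        if not 3 <= self.n_directions <= len(DIRECTIONS_13):
            raise ValueError(f"n_directions must be in [3, {len(DIRECTIONS_13)}]")
        if self.min_voxels < 1 or self.max_sets_per_channel < 1:
            raise ValueError("min_voxels and max_sets_per_channel must be >= 1")
        if not 1 <= self.min_directions_hit <= self.n_directions:
            raise ValueError("min_directions_hit must be in [1, n_directions]")


def _direction_offsets(
    direction: tuple[int, int, int],
    length_um: float,
    voxel_size_um: tuple[float, float, float],
) -> list[tuple[int, int, int]]:
    """Symmetric per-step (x, y, z) offsets along one direction, center excluded."""
    step_um = float(
        np.linalg.norm(np.array(direction) * np.array(voxel_size_um))
    )
    half = max(1, int(np.floor(length_um / (2.0 * step_um))))
    dx, dy, dz = direction
    return [
        (t * dx, t * dy, t * dz) for t in range(-half, half + 1) if t != 0
    ]


def dslt_segment(vol: Volume3D, params: SegmentationParams) -> np.ndarray:
    """Binary [z][y][x] foreground mask via direction-selective local
    thresholding.

    For each of ``n_directions`` orientations the local background is the
    mean along a centered line kernel (center voxel excluded; borders use
    edge replication, so a uniform volume yields an empty mask).  A voxel
    is foreground iff ``intensity > local_mean + local_offset`` in at least
    ``min_directions_hit`` orientations.  Purely local contrast makes the
    mask invariant to adding a constant everywhere.
    """
    if vol.data.size == 0:
        raise ValueError("empty volume")
    data = vol.data.astype(np.float32)
    sz, sy, sx = data.shape
    hits = np.zeros(data.shape, dtype=np.int16)
    for direction in DIRECTIONS_13[: params.n_directions]:
        offsets = _direction_offsets(
            direction, params.line_kernel_length_um, vol.space.voxel_size_um
        )
        px = max(abs(o[0]) for o in offsets)
        py = max(abs(o[1]) for o in offsets)
        pz = max(abs(o[2]) for o in offsets)
        if any(2 * p + 1 > n for p, n in ((px, sx), (py, sy), (pz, sz)) if p):
            raise ValueError(
                f"line kernel along {direction} longer than volume "
                f"{vol.data.shape}"
            )
        padded = np.pad(data, ((pz, pz), (py, py), (px, px)), mode="edge")
        acc = np.zeros_like(data)
        for ox, oy, oz in offsets:
            acc += padded[
                pz + oz: pz + oz + sz,
                py + oy: py + oy + sy,
                px + ox: px + ox + sx,
            ]
        local_mean = acc / len(offsets)
        hits += data > local_mean + params.local_offset
    return hits >= params.min_directions_hit


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def label_components(
    mask: np.ndarray, vol: Volume3D | None = None,
    space: AlignmentSpace | None = None,
) -> list[VoxelSet]:
    """26-connected components of a mask as voxel sets.

    Intensities come from ``vol`` when given, else 255.  Output ordering is
    deterministic: by size descending, then by lexically smallest
    (x, y, z) coordinate.
    """
    if vol is not None:
        space = vol.space
    if space is None:
        raise ValueError("either vol or space is required")
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    slices = ndimage.find_objects(labels)
    sets: list[VoxelSet] = []
    for k in range(1, n + 1):
        box = slices[k - 1]
        zz, yy, xx = np.nonzero(labels[box] == k)
        zz = zz + box[0].start
        yy = yy + box[1].start
        xx = xx + box[2].start
        coords = np.stack([xx, yy, zz], axis=1)
        inten = (
            vol.data[zz, yy, xx] if vol is not None
            else np.full(len(xx), 255, dtype=np.uint8)
        )
        sets.append(VoxelSet(space=space, coords=coords, intensities=inten))
    sets.sort(
        key=lambda s: (
            -len(s),
            min(map(tuple, s.coords.tolist())),
        )
    )
    return sets


def filter_components(
    sets: list[VoxelSet], params: SegmentationParams
) -> list[VoxelSet]:
    """Drop junk voxel sets; keep at most ``max_sets_per_channel`` largest.

    A set survives when it has >= ``min_voxels`` voxels, its longest
    bounding-box edge is >= ``min_bbox_extent_um`` and its elongation
    (longest/shortest bbox edge) is <= ``max_elongation``.  Idempotent;
    preserves the incoming order.
    """
    keep = [
        s for s in sets
        if len(s) >= params.min_voxels
        and max(s.descriptor.bbox_extent_um) >= params.min_bbox_extent_um
        and s.descriptor.elongation <= params.max_elongation
    ]
    cap = params.max_sets_per_channel
    if len(keep) > cap:
        largest = sorted(range(len(keep)), key=lambda i: (-len(keep[i]), i))[:cap]
        keep = [keep[i] for i in sorted(largest)]
    return keep


def voxelsets_to_cdms(
    sets: list[VoxelSet], lut: DepthLUT, space: AlignmentSpace,
    bit_depth: int = 8,
) -> list[CDMImage]:
    """Encode each voxel set as its own CDM (other voxels treated as empty)."""
    out = []
    for i, s in enumerate(sets):
        vol = np.zeros(space.shape_zyx, dtype=np.uint16)
        xx, yy, zz = s.coords[:, 0], s.coords[:, 1], s.coords[:, 2]
        vol[zz, yy, xx] = s.intensities
        cdm = encode_volume(
            Volume3D(space=space, data=vol.astype(
                np.uint8 if bit_depth == 8 else np.uint16), bit_depth=bit_depth),
            lut,
        )
        cdm.source_id = f"set{i}"
        out.append(cdm)
    return out


def segment_channel(
    vol: Volume3D, params: SegmentationParams, lut: DepthLUT
) -> tuple[list[VoxelSet], list[CDMImage]]:
    """Full per-channel pipeline: DSLT mask -> components -> junk filter ->
    per-set CDMs."""
    mask = dslt_segment(vol, params)
    sets = filter_components(label_components(mask, vol=vol), params)
    return sets, voxelsets_to_cdms(sets, lut, vol.space, bit_depth=vol.bit_depth)
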