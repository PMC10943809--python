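"""Depth-to-color encoding: LUT, volume projection, skeleton rasterization,
and mirror-flip augmentation.

A color depth MIP (CDM) collapses a 3D stack to 2D while keeping depth
information: each (x, y) pixel takes the color of the z slice holding the
column's maximum intensity, with the color's brightness modulated by that
intensity.  The depth lookup table (LUT) is an HSV hue ramp from 240°
(pure blue, slice 0 = anterior) to 0° (pure red, last slice = posterior) at
full saturation and value.  Rather than hard-coding any particular tool's
internal color table, the LUT is an explicit, serializable object so any
dataset can carry its own color convention.
"""

from __future__ import annotations

import colorsys
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_model import AlignmentSpace, CDMImage, Skeleton, Volume3D, VoxelSet

__all__ = [
    "DepthLUT",
    "DepthLUTError",
    "DecodeError",
    "BACKGROUND",
    "build_depth_lut",
    "encode_volume",
    "decode_depth",
    "depth_map",
    "luminance",
    "rasterize_skeleton",
    "mirror_cdm",
    "combine_mirror",
    "crosses_midline",
]

#: Sentinel returned by :func:`decode_depth` for background (black) pixels.
BACKGROUND = -1


class DepthLUTError(ValueError):
    """The requested LUT cannot be built (e.g. colors would collide)."""


class DecodeError(ValueError):
    """A pixel color does not correspond to any LUT entry."""


@dataclass(frozen=True)
class DepthLUT:
    """Bijective slice-index -> RGB lookup table.

    ``colors`` is an (n_slices, 3) uint8 array; entries are pairwise
    distinct so decoding is exact.  Intensity scaling is linear on the HSV
    value channel: an encoded pixel stores ``round(color * intensity/max)``,
    and decoding renormalizes the value channel before LUT inversion.
    """

    colors: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
        object.__setattr__(self, "colors", colors)
        index = {tuple(int(v) for v in c): k for k, c in enumerate(colors)}
        if len(index) != len(colors):
            raise DepthLUTError("LUT colors are not pairwise distinct")
        if len(colors) < 2:
            raise DepthLUTError("a depth LUT needs at least 2 slices")
        object.__setattr__(self, "_index", index)

    @property
    def n_slices(self) -> int:
        return len(self.colors)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"colors": self.colors.tolist()}, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "DepthLUT":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(colors=np.array(json.load(fh)["colors"], dtype=np.uint8))


def build_depth_lut(n_slices: int) -> DepthLUT:
    """Build the default anterior-blue to posterior-red hue-ramp LUT.

    Hue runs linearly from 240° at slice 0 to 0° at the last slice, at full
    saturation and value.  Raises :class:`DepthLUTError` when 8-bit RGB
    quantization cannot keep ``n_slices`` colors distinct (the 240° ramp
    holds at most ~1021 distinct quantized colors).
    """
    if not 2 <= n_slices <= 1024:
        raise DepthLUTError(f"n_slices must be in [2, 1024], got {n_slices}")
    hues = np.linspace(240.0, 0.0, n_slices) / 360.0
    colors = np.array(
        [[round(c * 255) for c in colorsys.hsv_to_rgb(h, 1.0, 1.0)] for h in hues],
        dtype=np.uint8,
    )
    try:
        return DepthLUT(colors=colors)
    except DepthLUTError as exc:
        raise DepthLUTError(
            f"{n_slices} slices exceed the distinct-color capacity of the hue ramp"
        ) from exc


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Brightness of RGB pixels as the HSV value channel (max of R, G, B).

    This is the channel the intensity scaling modulates, so it recovers the
    relative voxel intensity irrespective of depth hue.
    """
    return np.asarray(pixels).max(axis=-1)


def encode_volume(
    vol: Volume3D, lut: DepthLUT, intensity_threshold: int = 0
) -> CDMImage:
    """Project a volume to a CDM: per-column max intensity, depth as color.

    A pixel is background iff no voxel in its z column exceeds
    ``intensity_threshold``.  Ties between equal column maxima break toward
    the shallower slice (smaller z), deterministically.
    """
    if vol.space.shape_xyz[2] != lut.n_slices:
        raise ValueError(
            f"volume has {vol.space.shape_xyz[2]} slices but LUT has {lut.n_slices}"
        )
    data = vol.data
    peak = data.max(axis=0)
    argz = data.argmax(axis=0)  # first occurrence = shallowest slice
    fg = peak > intensity_threshold
    # brightness floor of 32/255 keeps every foreground hue decodable
    # under 8-bit quantization (worst-case rounding error ~4 per channel
    # after value renormalization)
    scale = np.maximum(peak.astype(np.float64) / vol.max_intensity, 32.0 / 255.0)
    rgb = np.rint(lut.colors[argz] * scale[..., None])
    rgb[~fg] = 0
    return CDMImage(space=vol.space, pixels=rgb.astype(np.uint8),
                    source_id=vol.channel_id or "", variant="original")


def _normalize_pixel(color: np.ndarray) -> tuple[int, int, int]:
    v = int(color.max())
    if v == 0:
        return (0, 0, 0)
    return tuple(int(round(int(c) * 255.0 / v)) for c in color)


def decode_depth(color, lut: DepthLUT, tolerance: int = 4) -> int:
    """Invert the LUT for one pixel: color -> z slice index.

    Black returns :data:`BACKGROUND`.  The pixel's value channel is
    normalized to full brightness first (undoing intensity scaling); exact
    LUT colors then decode exactly, and colors within ``tolerance``
    (Chebyshev distance, absorbing 8-bit rounding of dim pixels) decode to
    the nearest entry.  Anything else raises :class:`DecodeError`.
    """
    color = np.asarray(color, dtype=np.int64).reshape(3)
    norm = _normalize_pixel(color)
    if norm == (0, 0, 0):
        return BACKGROUND
    hit = lut._index.get(norm)
    if hit is not None:
        return hit
    diffs = np.abs(lut.colors.astype(np.int64) - np.array(norm)).max(axis=1)
    k = int(diffs.argmin())
    if diffs[k] <= tolerance:
        return k
    raise DecodeError(f"color {tuple(color)} does not decode under this LUT")


def depth_map(cdm: CDMImage, lut: DepthLUT, tolerance: int = 4) -> np.ndarray:
    """Vectorized decode of a whole CDM to an int16 [y][x] slice-index map.

    Background pixels map to :data:`BACKGROUND`.  Raises
    :class:`DecodeError` if any foreground pixel fails to decode.
    """
    px = cdm.pixels.astype(np.int64)
    v = px.max(axis=2)
    fg = v > 0
    out = np.full(v.shape, BACKGROUND, dtype=np.int16)
    if not fg.any():
        return out
    norm = np.rint(px[fg] * (255.0 / v[fg][:, None])).astype(np.int64)
    # exact pass via a dense RGB hash, nearest-within-tolerance fallback
    lutc = lut.colors.astype(np.int64)
    keys = (lutc[:, 0] << 16) | (lutc[:, 1] << 8) | lutc[:, 2]
    table = dict(zip(keys.tolist(), range(len(keys))))
    nkeys = (norm[:, 0] << 16) | (norm[:, 1] << 8) | norm[:, 2]
    idx = np.array([table.get(int(k), -2) for k in nkeys.tolist()], dtype=np.int64)
    miss = idx == -2
    if miss.any():
        d = np.abs(norm[miss][:, None, :] - lutc[None, :, :]).max(axis=2)
        near = d.argmin(axis=1)
        bad = d[np.arange(len(near)), near] > tolerance
        if bad.any():
            raise DecodeError(
                f"{int(bad.sum())} foreground pixels do not decode under this LUT"
            )
        idx[miss] = near
    out[fg] = idx.astype(np.int16)
    return out


# ---------------------------------------------------------------------------
# Skeleton rasterization
# ---------------------------------------------------------------------------

def rasterize_skeleton(
    skel: Skeleton, space: AlignmentSpace, radius_um: float
) -> Volume3D:
    """Rasterize a skeleton as a union of capsules of radius ``radius_um``.

    Every voxel whose reference point lies within ``radius_um`` of any edge
    segment (or of an isolated node) is set to max intensity.  Controlling
    the radius controls the rendered neuron diameter.  Geometry outside the
    space emits a warning and is clipped.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    vs = np.array(space.voxel_size_um, dtype=float)
    sx, sy, sz = space.shape_xyz
    out = np.zeros(space.shape_zyx, dtype=np.uint8)

    by_id = {n.node_id: n for n in skel.nodes}
    has_edge = set()
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    for n in skel.nodes:
        if n.parent_id != -1:
            p = by_id[n.parent_id]
            segments.append(
                (np.array([p.x, p.y, p.z]), np.array([n.x, n.y, n.z]))
            )
            has_edge.update((n.node_id, p.node_id))
    for n in skel.nodes:  # isolated nodes become spheres
        if n.node_id not in has_edge:
            pt = np.array([n.x, n.y, n.z])
            segments.append((pt, pt))

    clipped = False
    for p0, p1 in segments:
        lo = np.floor((np.minimum(p0, p1) - radius_um) / vs).astype(int)
        hi = np.ceil((np.maximum(p0, p1) + radius_um) / vs).astype(int)
        lo_c = np.maximum(lo, 0)
        hi_c = np.minimum(hi, [sx - 1, sy - 1, sz - 1])
        if np.any(lo < [0, 0, 0]) or np.any(hi > [sx - 1, sy - 1, sz - 1]):
            clipped = True
        if np.any(lo_c > hi_c):
            continue
        xs = np.arange(lo_c[0], hi_c[0] + 1)
        ys = np.arange(lo_c[1], hi_c[1] + 1)
        zs = np.arange(lo_c[2], hi_c[2] + 1)
        gx, gy, gz = np.meshgrid(xs * vs[0], ys * vs[1], zs * vs[2], indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1)
        d = p1 - p0
        dd = float(d @ d)
        if dd == 0.0:
            dist2 = ((pts - p0) ** 2).sum(axis=-1)
        else:
            t = np.clip(((pts - p0) @ d) / dd, 0.0, 1.0)
            near = p0 + t[..., None] * d
            dist2 = ((pts - near) ** 2).sum(axis=-1)
        inside = dist2 <= radius_um * radius_um
        ix, iy, iz = np.nonzero(inside)
        out[zs[iz], ys[iy], xs[ix]] = 255
    if clipped:
        warnings.warn("skeleton extends outside the alignment space; clipped")
    return Volume3D(space=space, data=out, bit_depth=8)


# ---------------------------------------------------------------------------
# Mirror-flip augmentation
# ---------------------------------------------------------------------------

def _mirror_index(space: AlignmentSpace) -> np.ndarray:
    """x -> mirrored x map about the midline, using pixel centers."""
    sx = space.shape_xyz[0]
    midline_px = space.midline_x_um / space.voxel_size_um[0]
    x = np.arange(sx)
    return np.rint(2.0 * midline_px - 1.0 - x).astype(int)


def mirror_cdm(cdm: CDMImage) -> CDMImage:
    """Reflect a CDM about the sagittal midline (an involution for the
    default centered midline)."""
    xm = _mirror_index(cdm.space)
    sx = cdm.space.shape_xyz[0]
    out = np.zeros_like(cdm.pixels)
    ok = (xm >= 0) & (xm < sx)
    out[:, xm[ok]] = cdm.pixels[:, ok]
    return cdm.with_pixels(out, variant="flipped")


def combine_mirror(cdm: CDMImage) -> CDMImage:
    """Union a CDM with its mirror image, pixelwise.

    Where both have foreground, the brighter pixel (HSV value channel) wins,
    mimicking maximum-intensity-projection semantics; ties keep the original.
    The result is the "combined/flipped" variant used to match bilateral
    expression patterns against single-hemisphere neurons.
    """
    m = mirror_cdm(cdm)
    take_m = luminance(m.pixels) > luminance(cdm.pixels)
    out = np.where(take_m[..., None], m.pixels, cdm.pixels)
    return cdm.with_pixels(out, variant="combined")


def crosses_midline(
    obj: Skeleton | VoxelSet, space: AlignmentSpace | None = None,
    band_um: float = 5.0
) -> bool:
    """True iff the object has presence on both sides of the midline,
    within a tolerance band of ``band_um`` µm.

    An object entirely on one side, farther than the band from the midline,
    does not cross; anything reaching the midline region does (mirroring is
    then a useful augmentation)."""
    if space is None:
        space = obj.space
    if isinstance(obj, Skeleton):
        xs = obj.coords_um()[:, 0]
    else:
        xs = obj.coords[:, 0] * space.voxel_size_um[0]
    if len(xs) == 0:
        return False
    m = space.midline_x_um
    return bool(xs.min() <= m + band_um and xs.max() >= m - band_um)
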