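"""Uni-directional shape-matching re-score for CDM search results.

The pixel kernel ranks by overlap alone, so a dense LM pattern can score
well against the wrong EM neuron.  The shape re-score penalizes EM pixels
the LM image cannot explain, asymmetrically: every EM foreground pixel
either

* has no LM foreground within ``xy_radius_um`` in XY -> one XY penalty;
* has XY support but every supporting LM pixel is displaced by more than
  ``z_mismatch_um`` in depth -> one Z penalty;
* otherwise counts as one positive match.

LM-only pixels are never penalized: an LM sample labels several neurons at
once, so LM signal absent from the EM neuron is expected, while EM branches
absent from the LM signal indicate a wrong match.  The final score is the
ratio positive / max(negative, 1); search results are re-sorted by it.

Defaults are an XY radius of 12 µm and a Z mismatch bound of 40 µm, both
converted through the alignment-space voxel size so they are
space-independent.  Boundaries are inclusive: exactly 12 µm away still
supports, exactly 40 µm of depth offset still matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cdm_encoding import BACKGROUND, DepthLUT, depth_map, mirror_cdm
from .cdm_search import MatchRecord
from .core_model import CDMImage, DimensionError

__all__ = [
    "ShapeParams",
    "ShapeResult",
    "xy_support_distance",
    "shape_penalties",
    "shape_score",
    "rerank",
]


@dataclass(frozen=True)
class ShapeParams:
    xy_radius_um: float = 12.0
    z_mismatch_um: float = 40.0

    def __post_init__(self) -> None:
        if self.xy_radius_um <= 0 or self.z_mismatch_um <= 0:
            raise ValueError("shape radii must be > 0")


@dataclass(frozen=True)
class ShapeResult:
    """Per-pair penalty tally.  negative = xy_penalties + z_penalties."""

    positive: int
    negative: int
    xy_penalties: int = 0
    z_penalties: int = 0

    def __post_init__(self) -> None:
        if self.positive < 0 or self.negative < 0:
            raise ValueError("counts must be >= 0")


def shape_score(result: ShapeResult) -> float:
    """positive / max(negative, 1) — finite and order-preserving even with
    zero penalties."""
    return result.positive / max(result.negative, 1)


def xy_support_distance(lm_cdm: CDMImage, lut: DepthLUT | None = None) -> np.ndarray:
    """Per-pixel Euclidean distance (µm) to the nearest LM foreground pixel.

    Exact (0) on foreground; all-infinite for a blank CDM.  Distances use
    the in-plane voxel size, so the field is in physical units.
    """
    fg = lm_cdm.foreground_mask()
    vsx, vsy, _ = lm_cdm.space.voxel_size_um
    if not fg.any():
        return np.full(fg.shape, np.inf)
    return ndimage.distance_transform_edt(~fg, sampling=(vsy, vsx))


def _disk_offsets(radius_um: float, vsx: float, vsy: float) -> np.ndarray:
    """(K, 2) integer (du=dy, dv=dx) offsets with physical norm <= radius."""
    rx = int(np.floor(radius_um / vsx))
    ry = int(np.floor(radius_um / vsy))
    dv, du = np.meshgrid(np.arange(-rx, rx + 1), np.arange(-ry, ry + 1))
    keep = (dv * vsx) ** 2 + (du * vsy) ** 2 <= radius_um**2 + 1e-9
    return np.stack([du[keep], dv[keep]], axis=1)


def shape_penalties(
    em_cdm: CDMImage, lm_cdm: CDMImage, params: ShapeParams, lut: DepthLUT,
) -> ShapeResult:
    """Classify every EM foreground pixel as positive, XY penalty or Z
    penalty against the LM CDM (see module docstring for the rule)."""
    if em_cdm.space != lm_cdm.space:
        raise DimensionError("EM and LM CDMs must share an alignment space")
    vsx, vsy, vsz = em_cdm.space.voxel_size_um
    em_z = depth_map(em_cdm, lut)
    lm_z = depth_map(lm_cdm, lut)
    ey, ex = np.nonzero(em_z != BACKGROUND)
    n_em = len(ey)
    if n_em == 0:
        return ShapeResult(positive=0, negative=0)

    offsets = _disk_offsets(params.xy_radius_um, vsx, vsy)
    pad_y = int(np.abs(offsets[:, 0]).max())
    pad_x = int(np.abs(offsets[:, 1]).max())
    lm_pad = np.full(
        (lm_z.shape[0] + 2 * pad_y, lm_z.shape[1] + 2 * pad_x),
        BACKGROUND, dtype=lm_z.dtype,
    )
    lm_pad[pad_y: pad_y + lm_z.shape[0], pad_x: pad_x + lm_z.shape[1]] = lm_z

    ez = em_z[ey, ex].astype(np.float64)
    min_dz_um = np.full(n_em, np.inf)
    for du, dv in offsets:
        nz = lm_pad[ey + pad_y + du, ex + pad_x + dv]
        has = nz != BACKGROUND
        if not has.any():
            continue
        dz = np.abs(ez[has] - nz[has]) * vsz
        min_dz_um[has] = np.minimum(min_dz_um[has], dz)

    supported = np.isfinite(min_dz_um)
    xy_pen = int((~supported).sum())
    z_pen = int((supported & (min_dz_um > params.z_mismatch_um + 1e-9)).sum())
    positive = n_em - xy_pen - z_pen
    return ShapeResult(
        positive=positive, negative=xy_pen + z_pen,
        xy_penalties=xy_pen, z_penalties=z_pen,
    )


def rerank(
    matches: list[MatchRecord],
    em_cdms: dict[str, CDMImage],
    lm_cdms: dict[str, CDMImage],
    params: ShapeParams,
    lut: DepthLUT,
    _cache: dict | None = None,
) -> list[MatchRecord]:
    """Attach a shape result to every record and re-sort by shape score.

    Records reference CDMs by id; whichever side of the record resolves in
    ``em_cdms`` provides the penalized (EM) pixels.  When a record was
    scored against the mirrored target, the target CDM is mirrored here too
    so the penalty geometry matches the kernel's.  Idempotent; ties break
    by matched pixels descending, then target id.
    """
    cache = _cache if _cache is not None else {}
    out = []
    for rec in matches:
        if rec.query_id in em_cdms:
            em, lm = em_cdms[rec.query_id], lm_cdms[rec.target_id]
            flipped_is_lm = True
        else:
            em, lm = em_cdms[rec.target_id], lm_cdms[rec.query_id]
            flipped_is_lm = False
        key = (em.source_id, em.variant, lm.source_id, lm.variant, rec.used_flip)
        res = cache.get(key)
        if res is None:
            # Mirror the scored-against-flip side, unless the record already
            # points at a pre-combined mirror variant (precomputed libraries).
            if rec.used_flip:
                if flipped_is_lm and lm.variant == "original":
                    lm = mirror_cdm(lm)
                elif not flipped_is_lm and em.variant == "original":
                    em = mirror_cdm(em)
            res = shape_penalties(em, lm, params, lut)
            cache[key] = res
        rec.shape_positive = res.positive
        rec.shape_negative = res.negative
        rec.shape_score = shape_score(res)
        out.append(rec)
    out.sort(key=lambda r: (-r.shape_score, -r.matched_pixels, r.target_id))
    return out
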