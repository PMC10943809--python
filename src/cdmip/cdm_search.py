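"""The CDM pixel-overlap matching kernel and library search.

Because a CDM folds depth into color, 3D shape similarity reduces to
counting overlapping 2D pixels whose decoded depths agree.  Two pixels
match when both are foreground (bright enough) and their decoded z slices
differ by at most ``z_slice_tolerance``.  The kernel score between two CDMs
is the maximum match count over a small square of XY translations and,
optionally, over a mirror flip of the target — the flip handles bilateral
expression imaged on the opposite hemisphere.

Scores are raw matched-pixel counts; a normalized variant
(matched / query foreground) is carried on each record for convenience but
ranking uses the raw count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cdm_encoding import BACKGROUND, DepthLUT, depth_map, luminance, mirror_cdm
from .core_model import CDMImage

__all__ = [
    "SearchParams",
    "MatchScore",
    "MatchRecord",
    "pixels_match",
    "match_count",
    "cdm_score",
    "search_library",
]


@dataclass(frozen=True)
class SearchParams:
    """Open parameters of the pixel kernel.

    xy_shift_px : search radius of the translation square (pixels).
    z_slice_tolerance : max |decoded depth difference| (slices) for a match.
    pixel_intensity_threshold : value-channel cutoff below which a pixel is
        treated as background.
    try_flip : also score against the mirrored target, keep the better.
    """

    xy_shift_px: int = 2
    z_slice_tolerance: int = 2
    pixel_intensity_threshold: int = 32
    try_flip: bool = False

    def __post_init__(self) -> None:
        if min(self.xy_shift_px, self.z_slice_tolerance,
               self.pixel_intensity_threshold) < 0:
            raise ValueError("search parameters must be non-negative")


@dataclass(frozen=True)
class MatchScore:
    matched_pixels: int
    best_shift: tuple[int, int]  # (dx, dy) applied to the target
    used_flip: bool = False

    def __post_init__(self) -> None:
        if self.matched_pixels < 0:
            raise ValueError("matched_pixels must be >= 0")


@dataclass
class MatchRecord:
    """A scored putative correspondence between two CDM images."""

    query_id: str
    target_id: str
    matched_pixels: int
    best_shift: tuple[int, int]
    used_flip: bool
    normalized_score: float = 0.0
    shape_positive: int | None = None
    shape_negative: int | None = None
    shape_score: float | None = None


def pixels_match(c1, c2, params: SearchParams, lut: DepthLUT) -> bool:
    """Single-pixel kernel: both foreground and depth-compatible."""
    l1 = int(luminance(np.asarray(c1)))
    l2 = int(luminance(np.asarray(c2)))
    if l1 < params.pixel_intensity_threshold or l2 < params.pixel_intensity_threshold:
        return False
    from .cdm_encoding import decode_depth

    z1 = decode_depth(c1, lut)
    z2 = decode_depth(c2, lut)
    if z1 == BACKGROUND or z2 == BACKGROUND:
        return False
    return abs(z1 - z2) <= params.z_slice_tolerance


def _profile(cdm: CDMImage, params: SearchParams, lut: DepthLUT):
    """(depths, fg) arrays for one CDM under the intensity threshold."""
    depths = depth_map(cdm, lut)
    fg = (depths != BACKGROUND) & (
        luminance(cdm.pixels) >= params.pixel_intensity_threshold
    )
    return depths, fg


def _count_shifted(
    qd: np.ndarray, qfg: np.ndarray, td: np.ndarray, tfg: np.ndarray,
    dx: int, dy: int, ztol: int,
) -> int:
    h, w = qd.shape
    ys, yt = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xt = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    q_fg = qfg[ys, xs]
    t_fg = tfg[yt, xt]
    both = q_fg & t_fg
    if not both.any():
        return 0
    dz = np.abs(qd[ys, xs].astype(np.int32) - td[yt, xt].astype(np.int32))
    return int((both & (dz <= ztol)).sum())


def match_count(
    query: CDMImage, target: CDMImage, dx: int, dy: int,
    params: SearchParams, lut: DepthLUT,
) -> int:
    """Matched-pixel count at one target translation (dx, dy).

    A query foreground pixel at (x, y) matches when the target pixel at
    (x + dx, y + dy) exists, is foreground, and is within the depth
    tolerance.  Out-of-bounds pairs never match.
    """
    qd, qfg = _profile(query, params, lut)
    td, tfg = _profile(target, params, lut)
    return _count_shifted(qd, qfg, td, tfg, dx, dy, params.z_slice_tolerance)


def _shift_order(radius: int) -> list[tuple[int, int]]:
    shifts = [
        (dx, dy)
        for dx in range(-radius, radius + 1)
        for dy in range(-radius, radius + 1)
    ]
    shifts.sort(key=lambda s: (s[0] * s[0] + s[1] * s[1], s))
    return shifts


def cdm_score(
    query: CDMImage, target: CDMImage, params: SearchParams, lut: DepthLUT,
) -> MatchScore:
    """Best match count over the translation square and optional flip.

    Ties break toward the smaller |shift| (then lexically smaller (dx, dy))
    and toward the unflipped target, so the result is a deterministic
    function of its inputs.
    """
    qd, qfg = _profile(query, params, lut)
    variants = [(_profile(target, params, lut), False)]
    if params.try_flip:
        variants.append((_profile(mirror_cdm(target), params, lut), True))
    return _score_profiles((qd, qfg), variants, params)


def _score_profiles(qprof, target_variants, params: SearchParams) -> MatchScore:
    """Kernel on precomputed (depths, fg) profiles; used by the precompute
    stage to avoid re-decoding CDMs for every pair."""
    qd, qfg = qprof
    best = MatchScore(matched_pixels=0, best_shift=(0, 0), used_flip=False)
    found = -1
    for (td, tfg), flipped in target_variants:
        for dx, dy in _shift_order(params.xy_shift_px):
            n = _count_shifted(qd, qfg, td, tfg, dx, dy, params.z_slice_tolerance)
            if n > found:
                found = n
                best = MatchScore(matched_pixels=n, best_shift=(dx, dy),
                                  used_flip=flipped)
    return best


def search_library(
    query: CDMImage, library: list[CDMImage], params: SearchParams,
    lut: DepthLUT,
) -> list[MatchRecord]:
    """Score a query against every library CDM; rank by matched pixels.

    The order is a deterministic total order: matched pixels descending,
    ties by target source_id ascending.
    """
    n_query_fg = int(_profile(query, params, lut)[1].sum())
    records = []
    for tgt in library:
        s = cdm_score(query, tgt, params, lut)
        records.append(
            MatchRecord(
                query_id=query.source_id,
                target_id=tgt.source_id,
                matched_pixels=s.matched_pixels,
                best_shift=s.best_shift,
                used_flip=s.used_flip,
                normalized_score=s.matched_pixels / max(n_query_fg, 1),
            )
        )
    records.sort(key=lambda r: (-r.matched_pixels, r.target_id))
    return records
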