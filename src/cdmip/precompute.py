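"""All-vs-all EM x LM precompute with flip-variant selection, bidirectional
match tables, driver-line grouping/capping and a deterministic local
shard-map-reduce execution contract.

An EM neuron contributes its original CDM and, when it crosses the brain
midline, a combined-mirror variant.  Every (EM neuron, LM image) pair is
scored once per variant and the higher-scoring variant is kept, so
bilateral LM expression matches the combined image while one-sided MCFO
expression matches the original.  Both search directions are derived from
the same comparison pass.  After shape re-scoring, LM matches for an EM
neuron are grouped by driver line, lines ordered by their best
representative, and capped at ``max_lines`` (default 300) distinct lines.

Execution is a partitioned map with an ordered reduce: results are
bit-identical for any worker count or batch size.
"""

from __future__ import annotations

import copy
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .cdm_encoding import DepthLUT
from .cdm_search import MatchRecord, SearchParams, _profile, _score_profiles
from .core_model import CDMImage, DimensionError
from .data_api import make_guid
from .shape_scoring import ShapeParams, rerank

__all__ = [
    "LibraryEntry",
    "MatchTable",
    "ShardError",
    "precompute_all",
    "group_and_cap",
    "shard_map_reduce",
]


@dataclass
class LibraryEntry:
    """One searchable CDM with its provenance.

    EM entries carry a body id in ``neuron_or_line_id``; LM entries a
    driver-line id plus the sample and channel/voxel-set index the CDM was
    segmented from.  ``image_id`` is a deterministic content-derived GUID,
    stable across runs and data versions.
    """

    cdm: CDMImage
    modality: str  # "EM" | "LM"
    neuron_or_line_id: str
    sample_id: str = ""
    index: int = 0
    image_id: str = field(default="")

    def __post_init__(self) -> None:
        if self.modality not in ("EM", "LM"):
            raise ValueError("modality must be 'EM' or 'LM'")
        if not self.neuron_or_line_id:
            raise ValueError(
                "EM entries need a body id, LM entries a driver-line id"
            )
        if not self.image_id:
            self.image_id = make_guid(
                self.modality, self.neuron_or_line_id, self.sample_id,
                str(self.index), self.cdm.variant,
            )
        self.cdm.source_id = self.image_id


@dataclass
class MatchTable:
    """Ranked match lists per query image, for one search direction."""

    direction: str  # "EM->LM" | "LM->EM"
    matches: dict[str, list[MatchRecord]]

    def n_pairs(self) -> int:
        return sum(len(v) for v in self.matches.values())


class ShardError(RuntimeError):
    """A map batch failed twice; carries the batch index."""


def shard_map_reduce(
    work: Sequence,
    fn: Callable,
    n_workers: int = 1,
    batch_size: int | None = None,
) -> list:
    """Apply ``fn`` to every work item in partitioned batches.

    The reduce concatenates batch results in batch order, so the output is
    identical to ``[fn(w) for w in work]`` for any ``n_workers`` and
    ``batch_size``.  A failing batch is retried once, then surfaced as
    :class:`ShardError` naming the batch.
    """
    work = list(work)
    if not work:
        return []
    if batch_size is None or batch_size < 1:
        batch_size = max(1, -(-len(work) // max(n_workers, 1) // 4) or 1)
    batches = [work[i: i + batch_size] for i in range(0, len(work), batch_size)]

    def run_batch(idx_batch):
        idx, batch = idx_batch
        for attempt in (0, 1):
            try:
                return [fn(item) for item in batch]
            except Exception:
                if attempt == 1:
                    raise
        raise AssertionError("unreachable")

    results: list[list] = [None] * len(batches)  # type: ignore[list-item]
    if n_workers <= 1:
        for i, b in enumerate(batches):
            try:
                results[i] = run_batch((i, b))
            except Exception as exc:
                raise ShardError(f"batch {i} failed after retry: {exc}") from exc
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            futures = [pool.submit(run_batch, (i, b)) for i, b in enumerate(batches)]
            for i, fut in enumerate(futures):
                try:
                    results[i] = fut.result()
                except Exception as exc:
                    raise ShardError(f"batch {i} failed after retry: {exc}") from exc
    merged: list = []
    for r in results:
        merged.extend(r)
    return merged


def group_and_cap(
    records: list[MatchRecord],
    line_of: dict[str, str],
    max_lines: int = 300,
    max_per_line: int | None = None,
) -> list[MatchRecord]:
    """Group LM matches by driver line, cap lines and per-line entries.

    ``records`` must already be in final (re-sorted) order.  Lines are
    ordered by their highest-ranking representative; at most ``max_lines``
    distinct lines survive, each contributing at most ``max_per_line``
    records (``None`` = unlimited; 1 keeps one image per line, useful when
    hunting split-line candidates).  Each line's internal order is
    preserved.
    """
    by_line: dict[str, list[MatchRecord]] = {}
    order: list[str] = []
    for rec in records:
        line = line_of[rec.target_id]
        if line not in by_line:
            if len(order) >= max_lines:
                continue
            by_line[line] = []
            order.append(line)
        by_line[line].append(rec)
    out: list[MatchRecord] = []
    for line in order:
        reps = by_line[line]
        if max_per_line is not None:
            reps = reps[:max_per_line]
        out.extend(reps)
    return out


def precompute_all(
    em_lib: list[LibraryEntry],
    lm_lib: list[LibraryEntry],
    search_params: SearchParams,
    shape_params: ShapeParams,
    lut: DepthLUT,
    max_lines: int = 300,
    max_per_line: int | None = None,
    n_workers: int = 1,
    batch_size: int | None = None,
) -> tuple[MatchTable, MatchTable]:
    """Score every EM x LM pair once and build both direction tables.

    EM variants of the same neuron (original + combined mirror) are
    deduplicated by the flip-max rule: the higher-scoring variant represents
    the pair (ties keep the original).  Shape re-scoring then re-sorts every
    list, and EM->LM lists are grouped/capped by driver line.  The whole
    computation is deterministic for any ``n_workers``/``batch_size``.
    """
    for e in em_lib:
        if e.modality != "EM":
            raise ValueError("em_lib contains a non-EM entry")
    for e in lm_lib:
        if e.modality != "LM":
            raise ValueError("lm_lib contains a non-LM entry")
    if not em_lib or not lm_lib:
        return (MatchTable("EM->LM", {}), MatchTable("LM->EM", {}))
    space = em_lib[0].cdm.space
    for e in em_lib + lm_lib:
        if e.cdm.space != space:
            raise DimensionError("libraries mix alignment spaces")

    # group EM variants per neuron (original first, deterministic)
    groups: dict[tuple[str, str], list[LibraryEntry]] = {}
    for e in em_lib:
        groups.setdefault((e.neuron_or_line_id, e.sample_id), []).append(e)
    group_keys = sorted(groups)
    for k in group_keys:
        groups[k].sort(key=lambda e: CDMImage.VARIANTS.index(e.cdm.variant))

    kernel = SearchParams(
        xy_shift_px=search_params.xy_shift_px,
        z_slice_tolerance=search_params.z_slice_tolerance,
        pixel_intensity_threshold=search_params.pixel_intensity_threshold,
        try_flip=False,  # variants are explicit library entries here
    )
    profiles = {
        e.image_id: _profile(e.cdm, kernel, lut) for e in em_lib + lm_lib
    }

    def score_pair(pair):
        gkey, lm = pair
        variants = groups[gkey]
        best_entry, best = None, None
        for v in variants:
            s = _score_profiles(
                profiles[v.image_id], [(profiles[lm.image_id], False)], kernel
            )
            if best is None or s.matched_pixels > best.matched_pixels:
                best_entry, best = v, s
        return MatchRecord(
            query_id=best_entry.image_id,
            target_id=lm.image_id,
            matched_pixels=best.matched_pixels,
            best_shift=best.best_shift,
            used_flip=best_entry.cdm.variant == "combined",
        )

    work = [(gkey, lm) for gkey in group_keys for lm in lm_lib]
    pair_records = shard_map_reduce(
        work, score_pair, n_workers=n_workers, batch_size=batch_size
    )

    em_cdms = {e.image_id: e.cdm for e in em_lib}
    lm_cdms = {e.image_id: e.cdm for e in lm_lib}
    line_of = {e.image_id: e.neuron_or_line_id for e in lm_lib}
    group_of = {}
    for gkey in group_keys:
        for v in groups[gkey]:
            group_of[v.image_id] = gkey

    cache: dict = {}
    em_to_lm: dict[str, list[MatchRecord]] = {}
    for gkey, recs in _split_by(pair_records, key=lambda r: group_of[r.query_id]):
        recs = sorted(recs, key=lambda r: (-r.matched_pixels, r.target_id))
        recs = rerank(recs, em_cdms, lm_cdms, shape_params, lut, _cache=cache)
        recs = group_and_cap(recs, line_of, max_lines=max_lines,
                             max_per_line=max_per_line)
        em_to_lm[groups[gkey][0].image_id] = recs

    lm_to_em: dict[str, list[MatchRecord]] = {}
    for lm_id, recs in _split_by(pair_records, key=lambda r: r.target_id):
        # same pass, viewed from the LM side: swap query/target roles
        flipped = [
            MatchRecord(
                query_id=lm_id, target_id=r.query_id,
                matched_pixels=r.matched_pixels, best_shift=r.best_shift,
                used_flip=r.used_flip,
            )
            for r in recs
        ]
        flipped.sort(key=lambda r: (-r.matched_pixels, r.target_id))
        lm_to_em[lm_id] = rerank(
            flipped, em_cdms, lm_cdms, shape_params, lut, _cache=cache
        )

    return (
        MatchTable("EM->LM", dict(sorted(em_to_lm.items()))),
        MatchTable("LM->EM", dict(sorted(lm_to_em.items()))),
    )


def _split_by(records, key):
    buckets: dict = {}
    for r in records:
        buckets.setdefault(key(r), []).append(copy.copy(r))
    return sorted(buckets.items())
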