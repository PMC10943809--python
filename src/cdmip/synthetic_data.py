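"""Synthetic aligned EM/LM datasets with ground-truth correspondence.

The generator emulates the inputs of the matching pipeline at desk scale:

* **EM side** — smooth random tube-like neurons in a shared toy alignment
  space, produced as SWC-style skeletons and rasterized at a controlled
  radius; a fraction are bilateral (a mirrored copy unioned across the
  midline), standing in for midline-crossing neurons.
* **LM side** — multi-channel confocal-like samples: each channel sums the
  volumes of the neurons stochastically assigned to it (emulating
  multi-color labeling that isolates 1-3 neurons per channel), scaled by a
  per-neuron brightness factor, plus constant background haze and additive
  Gaussian noise.

The default toy space is 256 x 128 x 64 voxels at 1 µm isotropic, so the
12 µm / 40 µm shape-score constants are 12 px / 40 slices — small enough
for fast tests, large enough for distinct morphologies.  All randomness is
behind explicit seeds and every dataset carries a manifest of the
parameters that produced it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .cdm_encoding import (
    DepthLUT,
    build_depth_lut,
    combine_mirror,
    crosses_midline,
    encode_volume,
    rasterize_skeleton,
)
from .core_model import AlignmentSpace, Skeleton, SkeletonNode, Volume3D
from .precompute import LibraryEntry, MatchTable
from .segmentation import SegmentationParams, segment_channel

__all__ = [
    "DEFAULT_SPACE",
    "NeuronParams",
    "LmNoiseParams",
    "SyntheticDataset",
    "generate_neuron",
    "generate_lm_sample",
    "generate_dataset",
    "evaluate_recovery",
]

DEFAULT_SPACE = AlignmentSpace(
    name="toy-unisex-256", shape_xyz=(256, 128, 64), voxel_size_um=(1.0, 1.0, 1.0)
)


@dataclass(frozen=True)
class NeuronParams:
    """Shape of one synthetic neuron.

    The centerline is a cubic spline through ``n_control`` points of a
    momentum random walk, sampled at ``n_nodes`` skeleton nodes and
    rendered as a tube of radius ``radius_um``.  ``bilateral`` unions a
    mirrored copy, pinning one endpoint to the midline so the neuron
    genuinely crosses it.
    """

    n_control: int = 6
    n_nodes: int = 40
    radius_um: float = 2.0
    step_um: float = 22.0
    margin_um: float = 10.0
    bilateral: bool = False


@dataclass(frozen=True)
class LmNoiseParams:
    """Confocal-channel corruption model: constant haze + Gaussian noise,
    with per-neuron brightness drawn uniformly from ``intensity_range``."""

    background_level: float = 20.0
    noise_sd: float = 5.0
    intensity_range: tuple[float, float] = (0.65, 0.95)


def _random_curve(
    rng: np.random.Generator, space: AlignmentSpace, params: NeuronParams,
    x_range: tuple[float, float],
) -> np.ndarray:
    """Momentum random walk -> spline -> (n_nodes, 3) µm points, in bounds."""
    _, sy, sz = space.shape_xyz
    _, vsy, vsz = space.voxel_size_um
    lo = np.array([x_range[0], params.margin_um, params.margin_um / 2])
    hi = np.array([x_range[1], sy * vsy - params.margin_um,
                   sz * vsz - params.margin_um / 2])
    pts = np.empty((params.n_control, 3))
    pts[0] = rng.uniform(lo, hi)
    heading = rng.normal(size=3)
    heading /= np.linalg.norm(heading)
    for i in range(1, params.n_control):
        turn = rng.normal(scale=0.6, size=3)
        heading = heading + turn
        heading /= np.linalg.norm(heading)
        nxt = pts[i - 1] + heading * params.step_um
        pts[i] = np.clip(nxt, lo, hi)
    t = np.linspace(0.0, 1.0, params.n_control)
    spline = CubicSpline(t, pts, axis=0)
    samples = spline(np.linspace(0.0, 1.0, params.n_nodes))
    return np.clip(samples, lo, hi)


def generate_neuron(
    seed: int,
    space: AlignmentSpace = DEFAULT_SPACE,
    params: NeuronParams = NeuronParams(),
) -> tuple[Skeleton, Volume3D]:
    """One reproducible synthetic neuron: (skeleton, rasterized volume).

    Identical seeds give identical output.  Unilateral neurons live in one
    randomly chosen hemisphere; bilateral ones end at the midline and union
    a mirrored copy of themselves.
    """
    rng = np.random.default_rng(seed)
    m = space.midline_x_um
    if params.bilateral:
        x_range = (params.margin_um, m)
    elif rng.random() < 0.5:
        x_range = (params.margin_um, m - 2.0)
    else:
        x_range = (m + 2.0, space.width_um - params.margin_um)
    curve = _random_curve(rng, space, params, x_range)
    if params.bilateral:
        curve[-1, 0] = m  # pin one endpoint to the midline

    nodes = [
        SkeletonNode(
            node_id=i + 1, node_type=3 if i else 1,
            x=float(p[0]), y=float(p[1]), z=float(p[2]),
            radius=params.radius_um, parent_id=i if i else -1,
        )
        for i, p in enumerate(curve)
    ]
    if params.bilateral:
        n = len(nodes)
        nodes += [
            SkeletonNode(
                node_id=n + i + 1, node_type=3 if i else 1,
                x=float(2 * m - p[0]), y=float(p[1]), z=float(p[2]),
                radius=params.radius_um, parent_id=n + i if i else -1,
            )
            for i, p in enumerate(curve)
        ]
    skel = Skeleton(nodes=nodes, space=space)
    vol = rasterize_skeleton(skel, space, params.radius_um)
    return skel, vol


def generate_lm_sample(
    neuron_volumes: list[Volume3D],
    channel_assignment: list[list[int]],
    noise: LmNoiseParams,
    seed: int,
    space: AlignmentSpace = DEFAULT_SPACE,
) -> tuple[list[Volume3D], list[list[int]]]:
    """Render one multi-channel LM sample.

    ``channel_assignment[c]`` lists indices into ``neuron_volumes`` that
    express in channel ``c``.  Each channel is the sum of its neurons'
    volumes (per-neuron brightness factor), plus constant background and
    Gaussian noise, clipped to the 8-bit range.  Returns the channels and
    the (unchanged) ground-truth channel -> neuron-index map.
    """
    rng = np.random.default_rng(seed)
    channels = []
    for c, members in enumerate(channel_assignment):
        acc = np.zeros(space.shape_zyx, dtype=np.float32)
        for idx in members:
            factor = rng.uniform(*noise.intensity_range)
            acc += neuron_volumes[idx].data.astype(np.float32) * factor
        acc += noise.background_level
        if noise.noise_sd > 0:
            acc += rng.normal(scale=noise.noise_sd, size=acc.shape)
        data = np.clip(np.rint(acc), 0, 255).astype(np.uint8)
        channels.append(
            Volume3D(space=space, data=data, bit_depth=8, channel_id=f"c{c}")
        )
    return channels, [list(m) for m in channel_assignment]


@dataclass
class SyntheticDataset:
    """A paired EM/LM toy dataset with ground truth.

    ``truth`` has one row per LM library entry:
    ``{"lm_image_id", "line", "sample", "channel", "set_index",
    "true_body"}`` where ``true_body`` is the best-overlapping EM body id,
    or None when the voxel set stems from a distractor neuron absent from
    the EM library.
    """

    space: AlignmentSpace
    lut: DepthLUT
    em_entries: list[LibraryEntry]
    lm_entries: list[LibraryEntry]
    truth: list[dict]
    skeletons: dict[str, Skeleton] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def generate_dataset(
    n_em: int = 50,
    n_lines: int = 20,
    samples_per_line: int = 1,
    seed: int = 7,
    space: AlignmentSpace = DEFAULT_SPACE,
    n_distractors: int = 5,
    bilateral_fraction: float = 0.25,
    distractor_prob: float = 0.15,
    noise: LmNoiseParams = LmNoiseParams(),
    seg_params: SegmentationParams = SegmentationParams(),
    channels_per_sample: int = 3,
) -> SyntheticDataset:
    """Full study dataset: EM CDM library, segmented LM CDM library, truth.

    EM library: ``n_em`` neurons (a ``bilateral_fraction`` of them
    bilateral), each an original CDM plus a combined-mirror variant when it
    crosses the midline.  LM side: ``n_lines`` driver lines, each
    expressing 1-3 neurons drawn from the EM pool (with probability
    ``distractor_prob`` a slot is filled by a distractor neuron that is not
    in the EM library); each sample distributes the line's neurons over
    ``channels_per_sample`` channels, which are rendered with noise and run
    through the segmentation pipeline to produce per-voxel-set LM CDMs.
    Every voxel set is mapped back to its best-overlapping source neuron.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    lut = build_depth_lut(space.shape_xyz[2])

    n_total = n_em + n_distractors
    neuron_seeds = rng.integers(0, 2**31 - 1, size=n_total)
    bilateral = rng.random(n_total) < bilateral_fraction
    ids = [f"em-{i:03d}" for i in range(n_em)] + [
        f"dx-{i:03d}" for i in range(n_distractors)
    ]
    skeletons: dict[str, Skeleton] = {}
    volumes: list[Volume3D] = []
    em_entries: list[LibraryEntry] = []
    for i in range(n_total):
        params = NeuronParams(bilateral=bool(bilateral[i]))
        skel, vol = generate_neuron(int(neuron_seeds[i]), space, params)
        skeletons[ids[i]] = skel
        volumes.append(vol)
        if i < n_em:
            cdm = encode_volume(vol, lut)
            em_entries.append(
                LibraryEntry(cdm=cdm, modality="EM", neuron_or_line_id=ids[i])
            )
            if crosses_midline(skel, space):
                em_entries.append(
                    LibraryEntry(
                        cdm=combine_mirror(cdm), modality="EM",
                        neuron_or_line_id=ids[i],
                    )
                )

    lm_entries: list[LibraryEntry] = []
    truth: list[dict] = []
    for li in range(n_lines):
        line_id = f"line-{li:03d}"
        k = int(rng.integers(1, 4))
        members: list[int] = []
        for _ in range(k):
            if n_distractors and rng.random() < distractor_prob:
                pick = int(rng.integers(n_em, n_total))
            else:
                pick = int(rng.integers(0, n_em))
            if pick not in members:
                members.append(pick)
        for sj in range(samples_per_line):
            sample_id = f"{line_id}-s{sj}"
            assignment: list[list[int]] = [[] for _ in range(channels_per_sample)]
            for idx in members:
                assignment[int(rng.integers(0, channels_per_sample))].append(idx)
            channels, _ = generate_lm_sample(
                volumes, assignment, noise, int(rng.integers(0, 2**31 - 1)), space
            )
            for c, chan in enumerate(channels):
                if not assignment[c]:
                    continue
                sets, cdms = segment_channel(chan, seg_params, lut)
                for k_set, (vset, cdm) in enumerate(zip(sets, cdms)):
                    entry = LibraryEntry(
                        cdm=cdm, modality="LM", neuron_or_line_id=line_id,
                        sample_id=sample_id, index=c * 100 + k_set,
                    )
                    lm_entries.append(entry)
                    xx, yy, zz = vset.coords[:, 0], vset.coords[:, 1], vset.coords[:, 2]
                    overlaps = {
                        ids[m]: int((volumes[m].data[zz, yy, xx] > 0).sum())
                        for m in assignment[c]
                    }
                    best = max(sorted(overlaps), key=lambda key: overlaps[key])
                    if overlaps[best] < 0.1 * len(vset):
                        best = None
                    truth.append(
                        {
                            "lm_image_id": entry.image_id,
                            "line": line_id,
                            "sample": sample_id,
                            "channel": c,
                            "set_index": k_set,
                            "true_body": best if (best or "").startswith("em-") else None,
                        }
                    )

    manifest = {
        "seed": seed,
        "space": {
            "name": space.name,
            "shape_xyz": list(space.shape_xyz),
            "voxel_size_um": list(space.voxel_size_um),
        },
        "n_em": n_em,
        "n_lines": n_lines,
        "samples_per_line": samples_per_line,
        "n_distractors": n_distractors,
        "bilateral_fraction": bilateral_fraction,
        "distractor_prob": distractor_prob,
        "channels_per_sample": channels_per_sample,
        "noise": asdict(noise),
        "segmentation": asdict(seg_params),
        "n_em_images": len(em_entries),
        "n_lm_images": len(lm_entries),
    }
    return SyntheticDataset(
        space=space, lut=lut, em_entries=em_entries, lm_entries=lm_entries,
        truth=truth, skeletons=skeletons, manifest=manifest,
    )


def evaluate_recovery(
    dataset: SyntheticDataset, lm_to_em: MatchTable
) -> tuple[int, int]:
    """Planted-neuron recovery: (n top-1 correct, n evaluable voxel sets).

    A voxel set counts as recovered when the top entry of its re-sorted
    LM->EM list is (a variant of) its true EM body.  Sets whose truth is a
    distractor (no EM counterpart) are excluded from the denominator.
    """
    body_of = {e.image_id: e.neuron_or_line_id for e in dataset.em_entries}
    n_ok = n_eval = 0
    for row in dataset.truth:
        if row["true_body"] is None:
            continue
        recs = lm_to_em.matches.get(row["lm_image_id"], [])
        if not recs:
            continue
        n_eval += 1
        if body_of.get(recs[0].target_id) == row["true_body"]:
            n_ok += 1
    return n_ok, n_eval
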