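# Methods

This note documents the models and procedures implemented in `cdmip`, the
parameter defaults and why they were chosen, the numerical conventions,
and what the synthetic benchmark does and does not demonstrate.

## Coordinate and intensity conventions

Volumes are indexed `[z][y][x]`, CDM images `[y][x]`, origin top-left, x
increasing rightward; x is the mirror axis. Physical coordinates are µm in
a shared alignment space; a µm coordinate maps to a voxel index by
`floor(coord / voxel_size)`, so a µm → voxel → µm round trip loses at most
one voxel per axis. Intensities are 8- or 12-bit unsigned, declared per
volume. The midline defaults to half the physical width, correct for
bilaterally symmetric templates, and is configurable for spaces where it
is not.

## Depth encoding

The depth LUT is an HSV hue ramp from 240° (pure blue, slice 0, anterior)
to 0° (pure red, last slice, posterior) at full saturation and value,
quantized to 8-bit RGB. The ramp holds ~1021 distinct quantized colors, so
LUTs up to 1024 slices are constructible and collisions raise an error
rather than silently merging depths. The LUT is an explicit, serializable
object (`DepthLUT.to_json`) so any dataset can carry its color convention.

Encoding takes the per-column maximum (ties break toward the shallower
slice, deterministically), and scales the LUT color linearly by
`intensity / max_intensity`. The brightness scale is floored at 32/255:
below that, 8-bit rounding distorts hue beyond recovery, and 32 is also
the default search-time foreground threshold, so nothing searchable is
affected. Decoding renormalizes the value channel and inverts the LUT
exactly, accepting nearest-neighbor matches within a Chebyshev distance of
4 (the worst-case rounding error at the brightness floor); anything
farther is a decode error. "Luminance" throughout the package means the
HSV value channel (max of R, G, B) — the quantity the intensity scaling
modulates.

## Skeleton rasterization

EM neurons arrive as SWC skeletons; rasterization renders the union of
capsules of a configurable radius (default 2 µm) around every edge
segment, with isolated nodes as spheres. Controlling the radius controls
the rendered neuron diameter, which is what makes skeleton-derived CDMs
comparable to LM signal of finite thickness. A voxel is set when its
reference point (index × voxel size) lies within the radius; the
implementation evaluates exact point-to-segment distances over per-segment
bounding boxes and is validated against a brute-force all-voxel oracle.

## DSLT segmentation

Direction-selective local thresholding circulates in the field as an idea
rather than a canonical algorithm listing, so this module implements that
idea directly: the local background at a voxel is the mean intensity along a
centered line kernel (center excluded), evaluated in up to 13 symmetric
3D directions (3 axes, 6 face diagonals, 4 space diagonals); a voxel is
foreground when it exceeds the local mean by `local_offset` in at least
`min_directions_hit` directions. Borders use edge replication, so a
uniform volume yields an empty mask and the mask is invariant to adding a
constant offset everywhere — the property that makes the method robust to
background haze. Defaults: kernel length 10 µm, offset 15 intensity
levels, 8 of 13 directions. These were chosen once so that a tube of
roughly neuron brightness (~150 over background) stands out against the
Gaussian noise model below; they are ordinary config parameters.

Components are 26-connected (thin neurites survive corner contacts),
ordered by size then lexically smallest coordinate. Junk filtering keeps
sets with ≥ 200 voxels, a longest bounding-box edge ≥ 10 µm and bbox
elongation ≤ 1000 (effectively unbounded by default); at most 8 sets per
channel survive, largest first. Shape-descriptor thresholds of this kind
are normally hand-tuned per dataset; these defaults are documented and
overridable.

## Pixel search kernel

Two pixels match when both are foreground (value channel ≥ 32/255) and
their decoded depths differ by at most `z_slice_tolerance` slices
(default 2). The pair score is the maximum match count over the
(2r+1)² translation square (default r = 2 px) and, when enabled, over the
mirrored target; ties break toward smaller |shift|, then the unflipped
target, making the kernel a deterministic function of its inputs. Earlier
interactive implementations of color-depth matching do not pin down a
single canonical pixel-comparison rule; matching on decoded-depth
difference is equivalent in intent and exactly testable, which is why it
is the definition here. Scores are raw matched-pixel counts; ranking ties break
by target id so orderings are total.

## Flip augmentation

Driver-line expression is typically bilateral while EM reconstruction
covers one hemisphere, so neurons that cross the midline (foreground on
both sides of the midline within a 5 µm band) get a combined-mirror
variant: the per-pixel union of the CDM and its reflection, brighter pixel
winning (MIP semantics). For every (EM neuron, LM image) pair the original
and combined variants are scored and the higher score represents the pair,
with ties kept on the original — one-sided LM expression then matches the
original while bilateral expression matches the combined image.

## Shape re-scoring

The pixel kernel rewards overlap but cannot punish EM structure the LM
image fails to explain. The shape score does, asymmetrically. For every
EM foreground pixel: if no LM foreground lies within `xy_radius_um`
(default 12 µm, boundary inclusive) it is an XY penalty; if LM support
exists but the minimum depth difference over all supporting pixels exceeds
`z_mismatch_um` (default 40 µm, boundary inclusive) it is a Z penalty;
otherwise it is a positive match. LM-only pixels never penalize, because
LM samples label several neurons at once. The score is
`positive / max(negative, 1)`; the clamped denominator keeps zero-penalty
scores finite and order-preserving (among zero-penalty candidates the
larger covered neuron wins). Both penalty types count equally into one
`negative` total, with per-type counts retained for inspection. All
distances are physical (µm through the voxel size), so the constants are
alignment-space independent. The implementation classifies pixels with a
precomputed in-disk offset table and is validated against an all-pairs
brute-force oracle; `xy_support_distance` exposes the exact Euclidean
distance field (scipy EDT) used for inspection.

Re-ranking attaches a shape result to every search record and re-sorts by
shape score (ties: matched pixels, then id). When a record was scored
against a mirrored target, the same mirroring is applied before computing
penalties — unless the record already points at a pre-combined variant
image, which is used as-is.

## Precompute, grouping, cap

All EM × LM pairs are scored once; both direction tables derive from that
single pass. The execution contract is a partitioned map with an ordered
reduce: work is split into contiguous batches, each batch retried once on
failure, and results merged in batch order — output is bit-identical for
any worker count or batch size (workers are threads; the heavy lifting is
in numpy). Pipeline order is: score all pairs, flip-max per pair, shape
re-rank, then group LM matches by driver line, order lines by their best
representative, and cap at 300 distinct lines (optionally limiting
representatives per line; 1 per line is the useful setting when hunting
intersection candidates). Capping after re-ranking means the cap operates
on the final ordering.

## Data model

Match metadata is served as a versioned static file tree (see the module
docstring of `data_api` for the layout). Image metadata is denormalized
into every match document so one fetch serves one query; long common
strings are interpolated as `$key` constants through the config's
constants table; every image has a content-derived (SHA-1) GUID, stable
across runs and versions. Schemas for the three document types are
authored here as JSON Schema files, shipped with the package and copied
into each version directory; validation uses a self-contained checker for
the schema subset those files use (type, required, properties, items,
enum, additionalProperties). Existing version directories are immutable:
writing version N+1 never touches a byte under N, and a rewrite of an
existing version is refused. Result documents for other match algorithms
are representable as sibling directories but are not computed here.

## Synthetic data generator

The generator emulates the study's input conditions at desk scale. The
default toy space is 256 × 128 × 64 voxels at 1 µm isotropic — the 12 µm
XY radius and 40 µm Z bound are then 12 px and 40 slices, and a dataset of
50 neurons fits in seconds of compute. Neurons are cubic splines through a
momentum random walk (6 control points, ~22 µm steps, 40 skeleton nodes),
rendered at 2 µm radius; 25% are bilateral, built by pinning one endpoint
to the midline and unioning a mirrored copy. LM channels are sums of
member-neuron volumes scaled by a per-neuron brightness in [0.65, 0.95],
plus constant background haze (20) and additive Gaussian noise (sd 5),
clipped to 8 bits — the simplest corruption model that exercises DSLT's
local-contrast logic. Driver lines express 1–3 neurons drawn from the EM
pool, with a 15% chance per slot of a distractor neuron absent from the
EM library; each sample spreads its neurons over 3 channels. Every voxel
set is mapped back to the source neuron with maximal voxel overlap (or to
none, if the best overlap is under 10%). All randomness sits behind
explicit seeds and every dataset carries a parameter manifest.

What the benchmark shows: that the full pipeline — simulate, segment,
encode, search, flip-max, shape re-rank — recovers the true source neuron
as the top hit for ≥ 90% of evaluable voxel sets (measured 92.3% at the
fixed benchmark seed; 100% at several others). What it does not show:
robustness to real LM artifacts (occlusion in the projection direction,
registration error, uneven staining, densely overlapping neurites), or
behavior at production scale (tens of thousands of neurons, billions of
comparisons). In particular the toy space is only 64 µm deep, so the
40 µm depth bound rarely discriminates there, and among zero-penalty
candidates the ratio score degenerates to the positive count — a known
failure mode on merged voxel sets that the realistic, much deeper spaces
mitigate.

## Problem sizes used in checks

The shipped checks run the planted-recovery study at 50 EM neurons × 20
driver lines (one sample per line, 3 channels), kernel-vs-oracle
agreement on 100 random 64×64 CDM pairs, depth round trips over all LUT
sizes from 2 to 512, the line cap on a 310-line fixture, and determinism
across 1 vs 4 workers — sizes chosen so the whole suite runs on a
single CPU in a couple of minutes while still exercising every stage.

## Known limitations

* Only 7-column SWC, single/multi-page grayscale TIFF and 8-bit RGB PNG
  are read; compressed 3D LM containers are out of scope.
* The mirror transform assumes the midline reflection maps the pixel grid
  onto itself (true for the default centered midline); off-grid midlines
  are rounded to the nearest pixel.
* DSLT here is the oriented-local-mean idea with line kernels; it is not
  a reproduction of any specific published implementation.
* `pixels_match`/`decode_depth` operate per pixel for clarity; the
  vectorized `depth_map` path is what search and scoring use internally.
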