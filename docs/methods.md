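# Methods

Definitions, conventions, and numerical choices. All array indexing is
`(z, y, x)`, 0-based; regions of interest are half-open; a voxel's center
sits at its integer coordinate. SWC coordinates are `(x, y, z)` in voxel
units of the level-0 grid.

## Morphology

An SWC file is parsed into a `NeuronTree` of `NeuronNode`s
(`id, type, x, y, z, radius, parent`). An extended dialect carries extra
per-node string labels via a header line
`#columns id,type,x,y,z,radius,parent,<label>...`; missing values are
written as `NA`. Writing uses `repr(float(v))`, so read → write round-trips
are byte-identical.

Node classes: **soma** = root (`parent == -1`), **branch** = ≥ 2 children,
**tip** = no children. A **segment** is the maximal path between two
critical points with only pass-through nodes in between. Segments partition
the edge set, which yields two exact identities used for validation:
segment lengths sum to the total tree length (machine precision), and a
full binary arbor with `t` tips has `2t − 1` segments.

## Tube voxelization and bounding boxes

A segment sweeps a tube: voxel `(z, y, x)` belongs to the foreground if its
center lies within distance `r(t)` of the centerline, where `r(t)` is the
linear interpolation of node radii along each polyline piece, and distances
are exact point-to-segment distances (closed condition, `≤`). The bounding
box of a polyline with radii is `origin = ceil(min(cᵢ − rᵢ))`,
`end = floor(max(cᵢ + rᵢ)) + 1` per axis, clipped to the volume; an
optional integer margin enlarges it.

## Per-segment SNR

With foreground voxel set `F` (tube ∩ volume) and background
`B = bbox \ F_neuron` (the box minus the **whole neuron's** foreground, so
a sibling branch crossing the box never counts as background):

```
B_crt = the ceil(0.2·|B|) brightest background voxels
SNR   = mean(I[F]) / (mean(I[B_crt]) + ε),   ε = 1e-6
```

Ties at the brightness cutoff are broken deterministically: descending
intensity, then ascending linear index in the full volume. Categories are
right-closed intervals at thresholds `(1.0, 1.2, 1.4)`: very-low ≤ 1.0 <
low ≤ 1.2 < mid ≤ 1.4 < high. A segment whose box has no background raises
`DegenerateSegmentError`; `profile_neuron` records such segments as skipped
and excludes them from the summary.

Neuron summary (lengths `Lᵢ`, ratios `sᵢ`):

* weighted SNR `Σ Lᵢ sᵢ / Σ Lᵢ`;
* VLSNR portion — length fraction in the very-low range;
* BASNR portion — length fraction with `sᵢ` strictly below the weighted
  SNR;
* VR portion — edge-length-weighted fraction whose child node carries
  `gen_method == "VR"`;
* `correlate_portions` regresses one portion on another across neurons
  (scipy `linregress`; zero variance in either variable raises
  `UndefinedCorrelationError`).

## Volume store

`read_volume`/`write_volume` support TIFF stacks (tifffile), a minimal NRRD
subset (raw and ASCII encodings, `sizes` listed fastest-first), and raw
little-endian blobs with a JSON sidecar. The pyramid store lays out
`meta.json` plus `L{level}/{bz}_{by}_{bx}.bin` chunks. Level `l` has
dimensions `ceil(d / 2ˡ)`; downsampling is 2×2×2 mean pooling averaged over
the voxels that exist (partial blocks at boundaries are not zero-padded),
quantized for integer dtypes with numpy's round-half-even. For float
dtypes, every level therefore preserves the global mean exactly up to
floating-point summation order. `fetch_roi` assembles any half-open box at
any level from the touched chunks, bit-exactly at level 0.

## Quality control

* **Sharp turns**: at each node, direction vectors are averaged over a
  `window` of edges on either side (clamped at root/branch/tip); an alert
  fires when the turning angle **strictly** exceeds the threshold
  (default 90°; 0° = straight, 180° = reversal). Zero-length edges are
  skipped. Larger windows suppress voxel-scale jitter.
* **Sholl**: crossings of the sphere of radius `r` about the soma are
  counted per edge with the half-open straddle `min(d₁,d₂) < r ≤
  max(d₁,d₂)`, so an endpoint exactly on the sphere is counted once.
* **Reconstruction distance**: tree A is resampled along its polylines at
  `sampling_step` (default 1.0); each sample takes its exact nearest
  distance to tree B's polyline pieces; reported as directed means A→B and
  B→A plus their average, and the same with z ignored (lateral variant,
  for anisotropic optics).
* **Length consistency** across annotators: `100·(max − min)/mean` of total
  lengths; **give-up rate**: failed fraction of attempt records.

## Collaboration model

A pure state machine with server-assigned contiguous sequence numbers
starting at 1. Commands (`add_segment`, `delete_segment`, `add_marker`,
`set_node_attr`) are validated *before* a sequence number is assigned, so
rejections consume no numbers and a log is always gap-free. `add_segment`
remaps client-local node ids to global ids in payload order; deleting a
node re-roots its children. Clients get colors from a fixed 32-entry
palette by join order; reconnects reuse the color. Logs are JSONL, one
command per line. `replay` of a log is a pure fold and, together with the
sorted, label-stable SWC exporter, is byte-identical across runs — the
basis for auditing multi-annotator sessions.

## Synthetic generator

`generate_morphology` grows a seeded random walk from a soma: step length
1.5, per-step heading jitter (Rodrigues rotation, default 10° s.d.),
reflection at the volume boundary, radii tapering geometrically from the
root, and a configurable number of branch events that split a tip into two
diverging children. All randomness comes from one `numpy` Generator, so a
spec is reproducible to the byte.

`render_volume` draws each segment as a **flat-top tube**: every voxel
satisfying exactly the voxelization criterion gets `bg_level +
fg_amplitude` (per-segment amplitudes may override, and may be negative as
long as the sum stays ≥ 0). Where tubes overlap, the brighter value wins.
Real fluorescence has a soft radial falloff; the flat profile is a
deliberate simplification so that the rendered foreground coincides voxel-
for-voxel with the profiler's foreground — this makes designed contrast
`(bg + fg)/bg` analytically recoverable (noise-free recovery is within
1e-3, observed ~1e-8) and turns the generator into a calibration
instrument rather than a visual mimic. An optional `edge_sigma` Gaussian
skirt outside the tube is available for softer images. Additional effects
modeled on fiber-tract micro-optical imaging: truncated-Gaussian background
noise, ~1-voxel signal dropout chunks (punctuated axons), bright clutter
blobs off the neuron, and a Gaussian blur along z for anisotropic optics.
Not modeled: optical PSF anisotropy in-plane, shading/vignetting, stitching
seams, autofluorescence gradients.

## Parameter defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| SNR ε | 1e-6 | guards the zero-background division without shifting realistic ratios |
| brightest-background fraction | 0.2 | the confusable background is its bright tail, not its mean |
| category thresholds | 1.0, 1.2, 1.4 | ratio 1.0 = indistinguishable from background; 20% steps grade difficulty |
| bbox margin | 0 | tight boxes keep the background local to the segment |
| turn threshold / window | 90° / 1 | right angles are anatomically plausible; beyond is suspect |
| Sholl step | caller-chosen | resolution/size trade-off is data-dependent |
| distance sampling step | 1.0 | one sample per voxel unit bounds discretization error by the voxel size |
| pyramid block size | 64³ | chunk ≈ 0.5 MB at 16-bit; balances I/O granularity and file count |

## Problem sizes and numerics

Tested volumes are up to 64³ in the suite; the pyramid and ROI machinery is
O(touched chunks) and extends to arbitrarily large stores. Voxelization and
rendering are vectorized over the segment bounding box only, so cost scales
with tube volume, not image volume. Distance computation chunks an
einsum-based all-pairs evaluation to bound memory. Accumulations use
float64 throughout; integer quantization uses round-half-even; all
randomness flows from explicit seeds; file outputs are written to a
temporary file and atomically renamed.
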