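"""Seeded generators of synthetic neuron morphologies and rendered image volumes.

The renderer emulates the hard regimes of sparse-labeled fMOST-like data:
bright tube signal along a tree morphology, intensity dropout along axons
("punctuated" tracts), constant-plus-Gaussian background, bright clutter
blobs, and anisotropic blur along z.  Every generator is a pure function of
its spec and seed, so fixtures are reproducible without stored data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morphology import NeuronNode, NeuronTree, decompose_segments
from .volume import Volume, _polyline_tube_mask, polyline_bbox

__all__ = [
    "MorphologySpec",
    "RenderSpec",
    "generate_morphology",
    "render_volume",
]


@dataclass(frozen=True)
class MorphologySpec:
    """Parameters of the random tree generator (all lengths in voxels)."""

    n_branch_events: int = 3
    segment_length_mean: float = 20.0
    segment_length_sd: float = 5.0
    tortuosity_deg: float = 10.0
    root_radius: float = 1.5
    radius_taper: float = 0.9
    step: float = 1.5
    dims: tuple[int, int, int] | None = None  # (z, y, x) bound, optional
    seed: int = 0

    def __post_init__(self):
        if self.segment_length_mean <= 0 or self.step <= 0:
            raise ValueError("segment lengths and step must be positive")
        if self.n_branch_events < 0:
            raise ValueError("n_branch_events must be non-negative")
        if self.root_radius <= 0 or not 0 < self.radius_taper <= 1:
            raise ValueError("invalid radius parameters")


@dataclass(frozen=True)
class RenderSpec:
    """Parameters of the volume renderer.

    fg_amplitude is the tube intensity added on top of bg_level, so the
    designed on-tube intensity is bg_level + fg_amplitude.  dropout_prob
    drops ~1-voxel chunks of centerline independently (punctuated axons);
    clutter_density is bright-blob count per 1000 voxels; z_blur_sigma is
    the anisotropic (z-axis) Gaussian blur in voxels.  edge_sigma > 0 adds a
    Gaussian intensity skirt beyond the tube radius (0 = hard-edged tube).
    """

    fg_amplitude: float = 100.0
    bg_level: float = 100.0
    bg_noise_sd: float = 0.0
    dropout_prob: float = 0.0
    clutter_density: float = 0.0
    z_blur_sigma: float = 0.0
    edge_sigma: float = 0.0
    dims: tuple[int, int, int] = (48, 48, 48)
    dtype: str = "float64"
    seed: int = 0

    def __post_init__(self):
        if self.bg_level < 0 or self.bg_level + self.fg_amplitude < 0:
            raise ValueError(
                "bg_level and the on-tube intensity bg_level + fg_amplitude "
                "must be non-negative"
            )
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _jitter(rng: np.random.Generator, d: np.ndarray, deg: float) -> np.ndarray:
    """Rotate direction d by a random angle ~ |N(0, deg)| about a random axis."""
    angle = math.radians(abs(rng.normal(0.0, deg)))
    axis = _unit(rng.normal(size=3))
    axis = _unit(np.cross(d, axis)) if np.linalg.norm(np.cross(d, axis)) > 1e-9 else _unit(rng.normal(size=3))
    c, s = math.cos(angle), math.sin(angle)
    return _unit(d * c + np.cross(axis, d) * s + axis * np.dot(axis, d) * (1 - c))


def generate_morphology(spec: MorphologySpec) -> NeuronTree:
    """Grow a random single-root tree by seeded directional random walk.

    The soma sits at the volume center (or the origin region when no bound
    is given); each branch event splits one growing tip into two divergent
    daughters.  Identical spec (including seed) yields an identical tree.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.dims is not None:
        lo = np.array([2.0, 2.0, 2.0])
        hi = np.array(spec.dims, dtype=float)[::-1] - 3.0  # (x, y, z) bound
        origin = (lo + hi) / 2
    else:
        lo = np.full(3, -np.inf)
        hi = np.full(3, np.inf)
        origin = np.zeros(3)

    nodes: list[NeuronNode] = [
        NeuronNode(1, 1, float(origin[0]), float(origin[1]), float(origin[2]),
                   spec.root_radius, -1)
    ]
    next_id = 2

    def grow_segment(parent_idx: int, direction: np.ndarray, radius: float) -> tuple[int, np.ndarray]:
        """Append one tortuous segment; returns (end node index, end direction)."""
        nonlocal next_id
        length = max(spec.step, rng.normal(spec.segment_length_mean, spec.segment_length_sd))
        n_steps = max(1, round(length / spec.step))
        idx = parent_idx
        d = direction
        for _ in range(n_steps):
            d = _jitter(rng, d, spec.tortuosity_deg)
            pos = nodes[idx].position + d * spec.step
            if spec.dims is not None:
                # reflect at bounds to keep the tree inside the volume
                for k in range(3):
                    if pos[k] < lo[k] or pos[k] > hi[k]:
                        d[k] = -d[k]
                        pos[k] = min(max(pos[k], lo[k]), hi[k])
            nodes.append(NeuronNode(
                next_id, 3, float(pos[0]), float(pos[1]), float(pos[2]),
                radius, nodes[idx].id,
            ))
            idx = len(nodes) - 1
            next_id += 1
        return idx, d

    # initial trunk from the soma
    tips: list[tuple[int, np.ndarray, float]] = []
    idx, d = grow_segment(0, _unit(rng.normal(size=3)), spec.root_radius)
    tips.append((idx, d, spec.root_radius))

    for _ in range(spec.n_branch_events):
        which = int(rng.integers(len(tips)))
        node_idx, d, radius = tips.pop(which)
        r_child = max(0.4, radius * spec.radius_taper)
        for sign in (1.0, -1.0):
            perp = _unit(np.cross(d, rng.normal(size=3)))
            child_dir = _unit(d + sign * 0.7 * perp)
            cidx, cd = grow_segment(node_idx, child_dir, r_child)
            tips.append((cidx, cd, r_child))

    return NeuronTree(nodes, provenance=f"synthetic morphology seed={spec.seed}")


def _chunk_polylines(
    pts: np.ndarray, radii: np.ndarray, chunk_len: float = 1.0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a polyline into contiguous sub-polylines of ~chunk_len arc length.

    The chunks' tubes union exactly to the full polyline tube, which keeps
    dropout-free rendering identical to the analytic voxelization.
    """
    chunks: list[tuple[np.ndarray, np.ndarray]] = []
    cur_p = [pts[0]]
    cur_r = [radii[0]]
    acc = 0.0
    for i in range(len(pts) - 1):
        a, b = pts[i], pts[i + 1]
        ra, rb = radii[i], radii[i + 1]
        ln = float(np.linalg.norm(b - a))
        if ln == 0:
            cur_p.append(b)
            cur_r.append(rb)
            continue
        pos = 0.0
        while pos < ln - 1e-12:
            take = min(ln - pos, chunk_len - acc)
            pos += take
            acc += take
            t = pos / ln
            cur_p.append(a + t * (b - a))
            cur_r.append(ra + t * (rb - ra))
            if acc >= chunk_len - 1e-12:
                chunks.append((np.array(cur_p), np.array(cur_r)))
                cur_p = [cur_p[-1]]
                cur_r = [cur_r[-1]]
                acc = 0.0
    if len(cur_p) > 1:
        chunks.append((np.array(cur_p), np.array(cur_r)))
    if not chunks:  # degenerate single-point polyline
        chunks.append((pts[:1], radii[:1]))
    return chunks


def render_volume(
    tree: NeuronTree,
    spec: RenderSpec,
    segment_amplitudes: dict[int, float] | None = None,
) -> Volume:
    """Render a neuron morphology into a synthetic image volume.

    Intensity = bg_level + Gaussian noise + tube signal + clutter, with the
    tube signal composed by maximum where neurites overlap.  The tube is
    flat-top: voxels whose centers lie within the interpolated node radius
    of the (kept) centerline chunks receive the full amplitude, so at zero
    noise the profiled foreground mean equals bg_level + amplitude exactly;
    edge_sigma adds an optional soft skirt outside the radius.

    ``segment_amplitudes`` overrides fg_amplitude per segment id (ids as
    returned by :func:`~neuritekit.morphology.decompose_segments`), enabling
    mixed-contrast neurons.
    """
    dims = spec.dims
    rng = np.random.default_rng(spec.seed)
    pos = np.array([[n.z, n.y, n.x] for n in tree.nodes])
    if np.any(pos < -0.5) or np.any(pos > np.array(dims) - 0.5):
        raise ValueError("tree extends outside the render dims")

    signal = np.zeros(dims, dtype=np.float64)
    claimed = np.zeros(dims, dtype=bool)  # voxels already owned by a tube
    for seg in decompose_segments(tree):
        amp = spec.fg_amplitude
        if segment_amplitudes is not None and seg.id in segment_amplitudes:
            amp = segment_amplitudes[seg.id]
        pts = np.array([[n.z, n.y, n.x] for n in seg.node_path], dtype=float)
        radii = np.array([n.radius for n in seg.node_path], dtype=float)
        if spec.dropout_prob > 0:
            # punctuated axons: drop ~1-voxel centerline chunks independently
            pieces = [
                (cpts, cradii)
                for cpts, cradii in _chunk_polylines(pts, radii)
                if rng.random() >= spec.dropout_prob
            ]
        else:
            # single exact tube; identical voxel set to voxelize_segment
            pieces = [(pts, radii)]
        for cpts, cradii in pieces:
            box = polyline_bbox(cpts, cradii)
            lo = np.maximum(np.array(box.origin), 0)
            hi = np.minimum(np.array(box.origin) + np.array(box.shape), np.array(dims))
            if np.any(hi <= lo):
                continue
            shape = tuple(int(v) for v in hi - lo)
            mask = _polyline_tube_mask(cpts, cradii, lo, shape)
            region = signal[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            cl = claimed[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            # fresh voxels take this tube's amplitude (which may be negative:
            # a neurite dimmer than background); where tubes overlap the
            # brighter one wins (max-composition)
            region[mask & ~cl] = amp
            np.maximum(region, amp, out=region, where=mask & cl)
            cl |= mask
            if spec.edge_sigma > 0:
                # soft skirt: amplitude decays with distance beyond the radius
                zz, yy, xx = np.meshgrid(
                    *(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij"
                )
                centers = np.stack([zz, yy, xx], axis=-1).astype(float)
                d_out = np.full(shape, np.inf)
                for i in range(max(1, len(cpts) - 1)):
                    a = cpts[i]
                    b = cpts[min(i + 1, len(cpts) - 1)]
                    ab = b - a
                    ab2 = float(ab @ ab)
                    t = (np.clip(((centers - a) @ ab) / ab2, 0, 1)
                         if ab2 > 0 else np.zeros(shape))
                    near = a + t[..., None] * ab
                    r_here = cradii[i] + t * (cradii[min(i + 1, len(cradii) - 1)] - cradii[i])
                    d_out = np.minimum(d_out, np.linalg.norm(centers - near, axis=-1) - r_here)
                skirt = amp * np.exp(-np.maximum(d_out, 0.0) ** 2 / (2 * spec.edge_sigma ** 2))
                np.maximum(region, skirt, out=region, where=~cl)

    # clutter: small bright Gaussian blobs, amplitudes between bg and fg levels
    n_vox = int(np.prod(dims))
    n_clutter = rng.poisson(spec.clutter_density * n_vox / 1000.0)
    for _ in range(n_clutter):
        c = rng.uniform(0, np.array(dims) - 1)
        amp = rng.uniform(0.25, 1.0) * spec.fg_amplitude
        sigma = rng.uniform(0.6, 1.5)
        lo = np.maximum(np.floor(c - 3 * sigma).astype(int), 0)
        hi = np.minimum(np.ceil(c + 3 * sigma).astype(int) + 1, np.array(dims))
        if np.any(hi <= lo):
            continue
        zz, yy, xx = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        blob = amp * np.exp(-d2 / (2 * sigma**2))
        region = signal[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        cl = claimed[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.maximum(region, blob, out=region, where=~cl)  # clutter never overwrites neurite

    vol = spec.bg_level + signal
    if spec.bg_noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.bg_noise_sd, size=dims)
    if spec.z_blur_sigma > 0:
        vol = ndimage.gaussian_filter1d(vol, spec.z_blur_sigma, axis=0)
    vol = np.maximum(vol, 0.0)  # intensities are non-negative
    dtype = np.dtype(spec.dtype)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        vol = np.round(np.clip(vol, info.min, info.max)).astype(dtype)
    else:
        vol = vol.astype(dtype)
    return Volume(vol)
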