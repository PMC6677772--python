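"""Per-segment and per-neuron image-quality (SNR) profiling.

For each neurite segment the foreground F is the set of voxels inside the
radius-swept tube, the background B is the segment's bounding box minus F,
and the critical background B_crt is the brightest 20% of B — a conservative
noise estimate that penalizes bright clutter next to the neurite.  The
segment statistic is

    SNR = mean(F) / (mean(B_crt) + eps)

with eps a small positive constant, and segments fall into four quality
ranges: very low (-inf, 1.0], low (1.0, 1.2], mid (1.2, 1.4], high (1.4, inf).
A neuron's overall SNR is the length-weighted mean of its segment SNRs;
VLSNR is the length fraction in the very-low range and BASNR the length
fraction below the neuron's own weighted average.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .morphology import NeuronTree, Segment, decompose_segments
from .volume import Volume, segment_bbox, voxelize_segment

__all__ = [
    "SNRConfig",
    "SNRCategory",
    "SegmentSNR",
    "NeuronSNRProfile",
    "DegenerateSegmentError",
    "profile_segment",
    "categorize_snr",
    "profile_neuron",
    "vr_portion",
    "correlate_portions",
]


class DegenerateSegmentError(ValueError):
    """Segment has no usable foreground or background voxels."""


class UndefinedCorrelationError(ValueError):
    """Zero variance in one of the correlated variables."""


class SNRCategory(str, enum.Enum):
    VERY_LOW = "very_low"
    LOW = "low"
    MID = "mid"
    HIGH = "high"


@dataclass(frozen=True)
class SNRConfig:
    """Profiling knobs.

    epsilon:
        The small positive constant added to the critical-background mean.
    bcrt_fraction:
        Fraction of background voxels (brightest first) forming B_crt;
        |B_crt| = ceil(bcrt_fraction * |B|), at least 1.
    bbox_margin:
        Voxels of padding added to the segment bounding box.
    thresholds:
        Right-closed category boundaries (very_low/low, low/mid, mid/high).
    """

    epsilon: float = 1e-6
    bcrt_fraction: float = 0.2
    bbox_margin: int = 0
    thresholds: tuple[float, float, float] = (1.0, 1.2, 1.4)

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0 < self.bcrt_fraction <= 1:
            raise ValueError("bcrt_fraction must be in (0, 1]")
        if not (self.thresholds[0] < self.thresholds[1] < self.thresholds[2]):
            raise ValueError("thresholds must be strictly increasing")


@dataclass
class SegmentSNR:
    segment_id: int
    f_mean: float
    bcrt_mean: float
    snr: float
    category: SNRCategory
    length: float
    n_foreground: int
    n_background: int
    clipped: bool = False


@dataclass
class NeuronSNRProfile:
    """Neuron-level SNR summary over the profiled segments."""

    segments: list[SegmentSNR]
    weighted_snr: float
    category_length_fractions: dict[SNRCategory, float]
    vlsnr_portion: float
    basnr_portion: float
    vr_portion: float | None = None
    skipped_segments: list[int] = field(default_factory=list)


def categorize_snr(snr: float, cfg: SNRConfig = SNRConfig()) -> SNRCategory:
    """Map an SNR value to its quality range (intervals right-closed)."""
    if not math.isfinite(snr):
        raise ValueError(f"non-finite SNR {snr}")
    t1, t2, t3 = cfg.thresholds
    if snr <= t1:
        return SNRCategory.VERY_LOW
    if snr <= t2:
        return SNRCategory.LOW
    if snr <= t3:
        return SNRCategory.MID
    return SNRCategory.HIGH


def _critical_background(
    intensities: np.ndarray, linear_idx: np.ndarray, fraction: float
) -> np.ndarray:
    """The ceil(fraction*|B|) brightest background intensities.

    Ties at the cut intensity are broken by ascending linear voxel index
    (after descending intensity), so the selected voxel set is deterministic.
    """
    k = max(1, math.ceil(fraction * len(intensities)))
    order = np.lexsort((linear_idx, -intensities.astype(np.float64)))
    return intensities[order[:k]]


def profile_segment(
    segment: Segment,
    vol: Volume,
    cfg: SNRConfig = SNRConfig(),
    exclude: set[tuple[int, int, int]] | None = None,
) -> SegmentSNR:
    """Compute the SNR record for one segment against an image volume.

    ``exclude`` optionally removes additional voxels from the background
    (the whole neuron's foreground when called from :func:`profile_neuron`,
    so that neighboring neurites do not masquerade as bright background).
    Raises :class:`DegenerateSegmentError` when the tube contributes no
    in-bounds voxel or the bounding box is entirely foreground.
    """
    dims = vol.dims
    fg = voxelize_segment(segment, dims)
    if not fg:
        raise DegenerateSegmentError(
            f"segment {segment.id}: no foreground voxel inside the volume"
        )
    box = segment_bbox(segment, margin=cfg.bbox_margin)
    lo = np.maximum(np.array(box.origin), 0)
    hi = np.minimum(np.array(box.origin) + np.array(box.shape), np.array(dims))
    clipped = bool(
        np.any(np.array(box.origin) < 0)
        or np.any(np.array(box.origin) + np.array(box.shape) > np.array(dims))
    )
    sub = vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float64)
    sub_shape = sub.shape
    fg_mask = np.zeros(sub_shape, dtype=bool)
    for z, y, x in fg:
        fg_mask[z - lo[0], y - lo[1], x - lo[2]] = True
    bg_mask = ~fg_mask
    if exclude:
        for z, y, x in exclude:
            if (lo[0] <= z < hi[0]) and (lo[1] <= y < hi[1]) and (lo[2] <= x < hi[2]):
                bg_mask[z - lo[0], y - lo[1], x - lo[2]] = False
    n_bg = int(bg_mask.sum())
    if n_bg == 0:
        raise DegenerateSegmentError(
            f"segment {segment.id}: bounding box fully foreground"
        )
    f_mean = float(sub[fg_mask].mean())
    # linear index within the full volume keeps the tie rule independent of bbox
    zz, yy, xx = np.nonzero(bg_mask)
    lin = ((zz + lo[0]) * dims[1] + (yy + lo[1])) * dims[2] + (xx + lo[2])
    bcrt = _critical_background(sub[bg_mask], lin, cfg.bcrt_fraction)
    bcrt_mean = float(bcrt.mean())
    snr = f_mean / (bcrt_mean + cfg.epsilon)
    return SegmentSNR(
        segment_id=segment.id,
        f_mean=f_mean,
        bcrt_mean=bcrt_mean,
        snr=snr,
        category=categorize_snr(snr, cfg),
        length=segment.length,
        n_foreground=len(fg),
        n_background=n_bg,
        clipped=clipped,
    )


def profile_neuron(
    tree: NeuronTree, vol: Volume, cfg: SNRConfig = SNRConfig()
) -> NeuronSNRProfile:
    """Profile every segment of a neuron and summarize at the neuron level.

    weighted_snr is the segment-length-weighted mean SNR; vlsnr_portion the
    length fraction whose segments fall in the very-low range; basnr_portion
    the length fraction with SNR strictly below weighted_snr.  Degenerate
    segments (no in-bounds foreground / no background) are excluded from the
    summary and reported in ``skipped_segments``.

    Each segment's background excludes the whole neuron's foreground, so a
    neighboring neurite passing through a segment's bounding box is not
    mistaken for bright background.
    """
    segments = decompose_segments(tree)
    neuron_fg: set[tuple[int, int, int]] = set()
    for seg in segments:
        neuron_fg |= voxelize_segment(seg, vol.dims)
    records: list[SegmentSNR] = []
    skipped: list[int] = []
    for seg in segments:
        try:
            records.append(profile_segment(seg, vol, cfg, exclude=neuron_fg))
        except DegenerateSegmentError:
            skipped.append(seg.id)
    if not records:
        raise DegenerateSegmentError("no profilable segment in this neuron")
    lengths = np.array([r.length for r in records])
    snrs = np.array([r.snr for r in records])
    total = float(lengths.sum())
    if total == 0:
        raise DegenerateSegmentError("all profilable segments have zero length")
    weighted = float((lengths * snrs).sum() / total)
    fractions = {c: 0.0 for c in SNRCategory}
    for r in records:
        fractions[r.category] += r.length / total
    vl = fractions[SNRCategory.VERY_LOW]
    ba = float(lengths[snrs < weighted].sum() / total)
    vr = None
    try:
        vr = vr_portion(tree)
    except MissingLabelError:
        pass
    return NeuronSNRProfile(
        segments=records,
        weighted_snr=weighted,
        category_length_fractions=fractions,
        vlsnr_portion=vl,
        basnr_portion=ba,
        vr_portion=vr,
        skipped_segments=skipped,
    )


class MissingLabelError(ValueError):
    """Nodes lack the gen_method label required for the VR portion."""


def vr_portion(tree: NeuronTree, label: str = "gen_method") -> float:
    """Length-weighted fraction of edges reconstructed in VR mode.

    Each edge is attributed to its child node's ``gen_method`` label
    ("VR" or "nonVR"); all child nodes must carry the label.
    """
    missing = [
        c for _, c in tree.edges() if label not in tree.node(c).labels
    ]
    if missing:
        raise MissingLabelError(
            f"nodes missing {label!r} label: {missing[:10]}"
        )
    vr_len = 0.0
    tot = 0.0
    for p, c in tree.edges():
        ln = tree.edge_length(p, c)
        tot += ln
        if tree.node(c).labels[label] == "VR":
            vr_len += ln
    if tot == 0:
        return 0.0
    return vr_len / tot


def correlate_portions(
    records: list[tuple[float, float]],
) -> dict[str, float]:
    """Pearson correlation and least-squares line of VR portion on VLSNR portion.

    ``records`` holds (vr_portion, vlsnr_portion) pairs; the regression is of
    vr (y) on vlsnr (x).  Returns {"pearson_r", "slope", "intercept", "n"}.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    arr = np.asarray(records, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite portion values")
    y = arr[:, 0]
    x = arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    res = stats.linregress(x, y)
    return {
        "pearson_r": float(res.rvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "n": len(records),
    }
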