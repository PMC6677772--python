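"""3-D image volumes, a chunked multi-resolution pyramid store, and tube voxelization.

Index order is (z, y, x), 0-based, with half-open ROIs throughout.  The
pyramid store holds mean-pooled levels (dims halved, ceiling, per level) in
a plain directory of little-endian raw chunk files plus one JSON metadata
file, so teravoxel-style ROI streaming can be exercised and tested at desk
scale.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .morphology import Segment

__all__ = [
    "Volume",
    "ROI",
    "PyramidStore",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "build_pyramid",
    "open_pyramid",
    "fetch_roi",
    "polyline_bbox",
    "segment_bbox",
    "voxelize_segment",
]


class VolumeFormatError(ValueError):
    """Unreadable, corrupt, or unsupported volume file."""


_SUPPORTED_DTYPES = ("uint8", "uint16", "float32", "float64")


@dataclass
class Volume:
    """A 3-D intensity grid indexed (z, y, x) with physical voxel size."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"volume must be 3-D, got shape {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise VolumeFormatError("volume contains non-finite intensities")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.data.shape)  # type: ignore[return-value]

    @property
    def dtype(self) -> np.dtype:
        return self.data.dtype


@dataclass(frozen=True)
class ROI:
    """Half-open region [origin, origin+shape) at a pyramid level, (z, y, x) order."""

    level: int
    origin: tuple[int, int, int]
    shape: tuple[int, int, int]

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("level must be non-negative")
        if any(o < 0 for o in self.origin) or any(s <= 0 for s in self.shape):
            raise ValueError("origin must be non-negative and shape positive")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(
            slice(o, o + s) for o, s in zip(self.origin, self.shape)
        )  # type: ignore[return-value]


# -- volume file I/O ---------------------------------------------------------

def _read_nrrd(path: Path) -> Volume:
    """Minimal NRRD reader: attached header, raw or ascii encoding, 3-D."""
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise VolumeFormatError(f"{path}: not an NRRD file")
        header: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, val = text.split(":", 1)
            header[key.strip().lower()] = val.lstrip("= ").strip()
        payload = fh.read()
    try:
        dtype = np.dtype(_NRRD_TYPES[header["type"].lower()])
        sizes = [int(v) for v in header["sizes"].split()]
        encoding = header.get("encoding", "raw").lower()
    except KeyError as exc:
        raise VolumeFormatError(f"{path}: missing NRRD header field {exc}") from None
    if len(sizes) != 3:
        raise VolumeFormatError(f"{path}: expected 3-D NRRD, sizes={sizes}")
    endian = header.get("endian", "little")
    if encoding == "raw":
        dt = dtype.newbyteorder("<" if endian == "little" else ">")
        arr = np.frombuffer(payload, dtype=dt)
    elif encoding in ("ascii", "text", "txt"):
        arr = np.array(payload.decode().split(), dtype=np.float64).astype(dtype)
    else:
        raise VolumeFormatError(f"{path}: unsupported NRRD encoding {encoding!r}")
    if arr.size != math.prod(sizes):
        raise VolumeFormatError(f"{path}: payload size mismatch")
    # NRRD sizes are fastest-first (x, y, z); our order is (z, y, x)
    data = arr.reshape(sizes[::-1]).astype(dtype)
    spacings = (1.0, 1.0, 1.0)
    if "spacings" in header:
        sp = [float(v) for v in header["spacings"].split()]
        spacings = tuple(sp[::-1])  # type: ignore[assignment]
    return Volume(data, voxel_size=spacings)


_NRRD_TYPES = {
    "uchar": "uint8", "unsigned char": "uint8", "uint8": "uint8",
    "ushort": "uint16", "unsigned short": "uint16", "uint16": "uint16",
    "float": "float32", "double": "float64",
}
_NRRD_NAMES = {"uint8": "uchar", "uint16": "ushort",
               "float32": "float", "float64": "double"}


def _write_nrrd(vol: Volume, path: Path) -> None:
    dt = str(vol.data.dtype)
    if dt not in _NRRD_NAMES:
        raise VolumeFormatError(f"unsupported dtype for NRRD: {dt}")
    dz, dy, dx = vol.dims
    header = (
        "NRRD0004\n"
        f"type: {_NRRD_NAMES[dt]}\n"
        "dimension: 3\n"
        f"sizes: {dx} {dy} {dz}\n"
        f"spacings: {vol.voxel_size[2]} {vol.voxel_size[1]} {vol.voxel_size[0]}\n"
        "encoding: raw\n"
        "endian: little\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(vol.data, dtype=np.dtype(dt).newbyteorder("<")).tobytes())


def read_volume(source: str | os.PathLike, format: str | None = None) -> Volume:
    """Read a 3-D volume from a TIFF stack, NRRD file, or raw+json pair.

    ``format`` is one of {"tiff_stack", "nrrd", "raw+json"}; when omitted it
    is inferred from the file suffix.
    """
    path = Path(source)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    if format is None:
        format = {
            ".tif": "tiff_stack", ".tiff": "tiff_stack",
            ".nrrd": "nrrd", ".bin": "raw+json", ".raw": "raw+json",
        }.get(path.suffix.lower())
        if format is None:
            raise VolumeFormatError(f"cannot infer format of {path}")
    if format == "tiff_stack":
        try:
            data = tifffile.imread(path)
        except Exception as exc:
            raise VolumeFormatError(f"{path}: unreadable TIFF ({exc})") from None
        if data.ndim == 2:
            data = data[None]
        if str(data.dtype) not in _SUPPORTED_DTYPES:
            raise VolumeFormatError(f"{path}: unsupported dtype {data.dtype}")
        return Volume(data)
    if format == "nrrd":
        return _read_nrrd(path)
    if format == "raw+json":
        meta_path = path.with_suffix(".json")
        try:
            meta = json.loads(meta_path.read_text())
            dims = tuple(meta["dims"])
            dtype = np.dtype(meta["dtype"]).newbyteorder("<")
            data = np.fromfile(path, dtype=dtype).reshape(dims)
        except Exception as exc:
            raise VolumeFormatError(f"{path}: bad raw+json pair ({exc})") from None
        return Volume(data.astype(meta["dtype"]),
                      voxel_size=tuple(meta.get("voxel_size", (1, 1, 1))))
    raise VolumeFormatError(f"unknown format {format!r}")


def write_volume(vol: Volume, dest: str | os.PathLike, format: str | None = None) -> None:
    """Write a volume; format inferred from suffix when omitted."""
    path = Path(dest)
    if format is None:
        format = {
            ".tif": "tiff_stack", ".tiff": "tiff_stack",
            ".nrrd": "nrrd", ".bin": "raw+json", ".raw": "raw+json",
        }.get(path.suffix.lower())
    if format == "tiff_stack":
        tifffile.imwrite(path, vol.data)
    elif format == "nrrd":
        _write_nrrd(vol, path)
    elif format == "raw+json":
        vol.data.astype(vol.data.dtype.newbyteorder("<")).tofile(path)
        path.with_suffix(".json").write_text(json.dumps({
            "dims": list(vol.dims),
            "dtype": str(vol.data.dtype),
            "voxel_size": list(vol.voxel_size),
        }))
    else:
        raise VolumeFormatError(f"unknown format {format!r}")


# -- multi-resolution pyramid -------------------------------------------------

def _downsample_mean(a: np.ndarray) -> np.ndarray:
    """2x2x2 mean pooling; partial boundary blocks averaged over existing voxels."""
    out_shape = tuple(-(-s // 2) for s in a.shape)
    acc = np.zeros(out_shape, dtype=np.float64)
    cnt = np.zeros(out_shape, dtype=np.int64)
    for oz in range(2):
        for oy in range(2):
            for ox in range(2):
                sub = a[oz::2, oy::2, ox::2]
                sl = tuple(slice(0, s) for s in sub.shape)
                acc[sl] += sub
                cnt[sl] += 1
    return acc / cnt


def _quantize(a: np.ndarray, dtype: np.dtype) -> np.ndarray:
    if np.issubdtype(dtype, np.integer):
        return np.round(a).astype(dtype)  # np.round is half-even
    return a.astype(dtype)


class PyramidStore:
    """Chunked multi-resolution store on disk.

    Layout: ``meta.json`` at the root plus ``L{level}/{bz}_{by}_{bx}.bin``
    chunk files holding little-endian raw voxels in (z, y, x) order.  Level 0
    reproduces the source volume exactly; level l+1 is the 2x2x2 mean-pool of
    level l (half-even rounding for integer dtypes).
    """

    def __init__(self, root: str | os.PathLike):
        self.root = Path(root)
        meta_path = self.root / "meta.json"
        if not meta_path.exists():
            raise VolumeFormatError(f"{self.root}: not a pyramid store (no meta.json)")
        self.meta = json.loads(meta_path.read_text())

    @property
    def n_levels(self) -> int:
        return int(self.meta["n_levels"])

    @property
    def block_size(self) -> tuple[int, int, int]:
        return tuple(self.meta["block_size"])

    def level_dims(self, level: int) -> tuple[int, int, int]:
        if not 0 <= level < self.n_levels:
            raise ValueError(f"level {level} out of range [0, {self.n_levels})")
        return tuple(self.meta["level_dims"][level])

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(self.meta["dtype"])

    def _block_path(self, level: int, bz: int, by: int, bx: int) -> Path:
        return self.root / f"L{level}" / f"{bz}_{by}_{bx}.bin"

    def read_block(self, level: int, bz: int, by: int, bx: int) -> np.ndarray:
        dims = self.level_dims(level)
        bs = self.block_size
        origin = (bz * bs[0], by * bs[1], bx * bs[2])
        if any(o >= d for o, d in zip(origin, dims)):
            raise ValueError(f"block ({bz},{by},{bx}) out of range at level {level}")
        shape = tuple(min(b, d - o) for b, d, o in zip(bs, dims, origin))
        raw = np.fromfile(
            self._block_path(level, bz, by, bx),
            dtype=self.dtype.newbyteorder("<"),
        )
        return raw.reshape(shape).astype(self.dtype)

    def read_level(self, level: int) -> np.ndarray:
        dims = self.level_dims(level)
        bs = self.block_size
        out = np.empty(dims, dtype=self.dtype)
        nblocks = [-(-d // b) for d, b in zip(dims, bs)]
        for bz in range(nblocks[0]):
            for by in range(nblocks[1]):
                for bx in range(nblocks[2]):
                    blk = self.read_block(level, bz, by, bx)
                    z0, y0, x0 = bz * bs[0], by * bs[1], bx * bs[2]
                    out[z0:z0 + blk.shape[0], y0:y0 + blk.shape[1],
                        x0:x0 + blk.shape[2]] = blk
        return out


def build_pyramid(
    vol: Volume,
    root: str | os.PathLike,
    block_size: tuple[int, int, int] = (32, 32, 32),
    n_levels: int = 3,
) -> PyramidStore:
    """Write a multi-resolution pyramid of ``vol`` under ``root``.

    Raises if ``n_levels`` would produce an empty level (all level dims are
    at least 1 by construction, so any n_levels >= 1 is valid; the guard
    rejects n_levels < 1).
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if any(b < 1 for b in block_size):
        raise ValueError("block_size must be positive")
    rootp = Path(root)
    rootp.mkdir(parents=True, exist_ok=True)
    level_dims = []
    level_data = vol.data
    dtype = vol.data.dtype
    for level in range(n_levels):
        level_dims.append([int(s) for s in level_data.shape])
        ldir = rootp / f"L{level}"
        ldir.mkdir(exist_ok=True)
        bs = block_size
        nblocks = [-(-d // b) for d, b in zip(level_data.shape, bs)]
        for bz in range(nblocks[0]):
            for by in range(nblocks[1]):
                for bx in range(nblocks[2]):
                    z0, y0, x0 = bz * bs[0], by * bs[1], bx * bs[2]
                    blk = level_data[z0:z0 + bs[0], y0:y0 + bs[1], x0:x0 + bs[2]]
                    np.ascontiguousarray(
                        blk, dtype=dtype.newbyteorder("<")
                    ).tofile(ldir / f"{bz}_{by}_{bx}.bin")
        if level + 1 < n_levels:
            level_data = _quantize(_downsample_mean(level_data), dtype)
    meta = {
        "format_version": 1,
        "n_levels": n_levels,
        "block_size": list(block_size),
        "level_dims": level_dims,
        "dtype": str(dtype),
        "downsample": "mean-2x2x2-halfeven",
        "voxel_size": list(vol.voxel_size),
    }
    (rootp / "meta.json").write_text(json.dumps(meta, indent=1))
    return PyramidStore(rootp)


def open_pyramid(root: str | os.PathLike) -> PyramidStore:
    return PyramidStore(root)


def fetch_roi(store: PyramidStore, roi: ROI) -> Volume:
    """Fetch the contiguous sub-grid of a pyramid level; out-of-bounds is an error."""
    dims = store.level_dims(roi.level)
    end = tuple(o + s for o, s in zip(roi.origin, roi.shape))
    if any(e > d for e, d in zip(end, dims)):
        raise ValueError(
            f"ROI {roi.origin}+{roi.shape} exceeds level {roi.level} dims {dims}"
        )
    bs = store.block_size
    out = np.empty(roi.shape, dtype=store.dtype)
    b_lo = [o // b for o, b in zip(roi.origin, bs)]
    b_hi = [-(-e // b) for e, b in zip(end, bs)]
    for bz in range(b_lo[0], b_hi[0]):
        for by in range(b_lo[1], b_hi[1]):
            for bx in range(b_lo[2], b_hi[2]):
                blk = store.read_block(roi.level, bz, by, bx)
                bo = (bz * bs[0], by * bs[1], bx * bs[2])
                src = tuple(
                    slice(max(0, ro - o), min(sh, ro + rs - o))
                    for o, sh, ro, rs in zip(bo, blk.shape, roi.origin, roi.shape)
                )
                dst = tuple(
                    slice(max(0, o - ro), max(0, o - ro) + (s.stop - s.start))
                    for o, ro, s in zip(bo, roi.origin, src)
                )
                out[dst] = blk[src]
    vs = store.meta.get("voxel_size", (1, 1, 1))
    scale = 2 ** roi.level
    return Volume(out, voxel_size=tuple(v * scale for v in vs))


# -- segment geometry ---------------------------------------------------------

def polyline_bbox(pts_zyx: np.ndarray, radii: np.ndarray, margin: int = 0) -> ROI:
    """Tight voxel box covering a radius-expanded polyline, (z, y, x) order.

    Bounds cover every voxel whose center can lie inside the sphere-swept
    tube: origin = ceil(min(coord - radius)), end = floor(max(coord +
    radius)) + 1, then expanded by ``margin`` and clipped below at 0.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    pts_zyx = np.asarray(pts_zyx, dtype=float)
    radii = np.asarray(radii, dtype=float)
    lo = np.ceil((pts_zyx - radii[:, None]).min(axis=0)).astype(int) - margin
    hi = np.floor((pts_zyx + radii[:, None]).max(axis=0)).astype(int) + 1 + margin
    lo = np.maximum(lo, 0)
    hi = np.maximum(hi, lo + 1)
    return ROI(level=0, origin=tuple(int(v) for v in lo),
               shape=tuple(int(h - l) for h, l in zip(hi, lo)))


def segment_bbox(segment: Segment, margin: int = 0) -> ROI:
    """Tight axis-aligned box around the radius-expanded segment.

    Clipping to volume dims happens at use time (ROIs themselves are
    volume-agnostic).
    """
    if not segment.node_path:
        raise ValueError("empty segment")
    pts = np.array([[n.z, n.y, n.x] for n in segment.node_path], dtype=float)
    radii = np.array([n.radius for n in segment.node_path], dtype=float)
    return polyline_bbox(pts, radii, margin=margin)


def _polyline_tube_mask(
    pts_zyx: np.ndarray, radii: np.ndarray, origin: np.ndarray, shape: tuple[int, ...]
) -> np.ndarray:
    """Boolean mask over a local grid: voxel centers within the interpolated
    radius of the polyline (per linear piece, endpoint-clamped projection)."""
    zz, yy, xx = np.meshgrid(
        np.arange(origin[0], origin[0] + shape[0]),
        np.arange(origin[1], origin[1] + shape[1]),
        np.arange(origin[2], origin[2] + shape[2]),
        indexing="ij",
    )
    centers = np.stack([zz, yy, xx], axis=-1).astype(float)  # (Z,Y,X,3)
    mask = np.zeros(shape, dtype=bool)
    if len(pts_zyx) == 1:
        d = np.linalg.norm(centers - pts_zyx[0], axis=-1)
        return d <= radii[0]
    for i in range(len(pts_zyx) - 1):
        a, b = pts_zyx[i], pts_zyx[i + 1]
        ab = b - a
        ab2 = float(ab @ ab)
        if ab2 == 0.0:
            t = np.zeros(shape)
        else:
            t = np.clip(((centers - a) @ ab) / ab2, 0.0, 1.0)
        nearest = a + t[..., None] * ab
        d = np.linalg.norm(centers - nearest, axis=-1)
        r = radii[i] + t * (radii[i + 1] - radii[i])
        mask |= d <= r
    return mask


def voxelize_segment(
    segment: Segment, dims: tuple[int, int, int]
) -> set[tuple[int, int, int]]:
    """Voxels (z, y, x) whose centers lie inside the segment's sphere-swept tube.

    Distance is measured to the polyline through the node positions, with
    the radius linearly interpolated along each piece; voxel centers sit at
    integer coordinates.  Returns an empty set when the tube misses ``dims``.
    """
    if not segment.node_path:
        raise ValueError("empty segment")
    pts = np.array([[n.z, n.y, n.x] for n in segment.node_path], dtype=float)
    radii = np.array([n.radius for n in segment.node_path], dtype=float)
    box = segment_bbox(segment)
    lo = np.array(box.origin)
    hi = lo + np.array(box.shape)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(dims))
    if np.any(hi <= lo):
        return set()
    shape = tuple(int(v) for v in hi - lo)
    mask = _polyline_tube_mask(pts, radii, lo, shape)
    zz, yy, xx = np.nonzero(mask)
    return {
        (int(z + lo[0]), int(y + lo[1]), int(x + lo[2]))
        for z, y, x in zip(zz, yy, xx)
    }
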