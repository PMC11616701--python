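"""Frame-sequence, results-table, and configuration I/O.

Supported frame containers: multi-page grayscale TIFF, directories of
lexicographically ordered single-frame images (PNG/TIFF), and a documented
little-endian raw stream.  All sequence readers are lazy: frames are decoded
on access, so memory use is bounded by a constant number of frames.

Raw stream layout (little-endian):
    bytes 0-3   magic ``VDCS``
    u32         width (px)
    u32         height (px)
    u32         bit depth (8 or 16)
    u32         frame count
    f64         frame rate (Hz)
    frames      row-major, one after another, native 8/16-bit unsigned

Coordinate convention used throughout the package: pixel indices are 0-based,
(x, y) = (column, row), and physical positions in μm are measured from the
center of the top-left ROI pixel (x = col * pixel_size_um).

Results tables are CSV with a mandatory ``# vdcyto-results v1`` first line
(schema version stamp), comma separator, '.' decimal, UTF-8; numeric columns
are written with 12 significant digits so all measurements round-trip.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .synth import ImagingConfig, PopulationSpec, SyntheticTruth, TruthManifest

__all__ = [
    "FormatError",
    "SchemaError",
    "FrameSequence",
    "ArraySequence",
    "open_sequence",
    "write_frames",
    "RESULTS_COLUMNS",
    "SCHEMA_VERSION",
    "empty_results",
    "write_results",
    "read_results",
    "config_to_json",
    "config_from_json",
    "manifest_to_json",
]

_RAW_MAGIC = b"VDCS"
_RAW_HEADER = struct.Struct("<4sIIIId")


class FormatError(Exception):
    """A frame container or table violates the documented format."""


class SchemaError(FormatError):
    """A results table carries an unknown or missing schema version."""


class FrameSequence:
    """Lazy, indexable sequence of equally sized grayscale frames."""

    config: ImagingConfig | None
    source: str

    def __len__(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    def __getitem__(self, i: int) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return tuple(self[0].shape)  # type: ignore[return-value]


class ArraySequence(FrameSequence):
    """In-memory frame stack (the generator's native output)."""

    def __init__(self, frames: np.ndarray, config: ImagingConfig | None = None):
        frames = np.asarray(frames)
        if frames.ndim != 3:
            raise FormatError("expected an (n_frames, height, width) array")
        self._frames = frames
        self.config = config
        self.source = "array"

    def __len__(self) -> int:
        return self._frames.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self._frames[i]


class _TiffSequence(FrameSequence):
    def __init__(self, path: Path, config: ImagingConfig | None):
        self._tif = tifffile.TiffFile(str(path))
        self._n = len(self._tif.pages)
        self.config = config
        self.source = str(path)
        first = self._tif.pages[0]
        self._shape = first.shape
        if first.dtype not in (np.dtype("uint8"), np.dtype("uint16")):
            raise FormatError(f"unsupported bit depth: {first.dtype}")

    def __len__(self) -> int:
        return self._n

    def __getitem__(self, i: int) -> np.ndarray:
        frame = self._tif.pages[i].asarray()
        if frame.shape != self._shape:
            raise FormatError("mixed frame dimensions in TIFF stack")
        return frame


class _DirSequence(FrameSequence):
    def __init__(self, path: Path, config: ImagingConfig | None):
        exts = {".png", ".tif", ".tiff"}
        self._files = sorted(p for p in path.iterdir() if p.suffix.lower() in exts)
        if not self._files:
            raise FormatError(f"no frame images found in {path}")
        self.config = config
        self.source = str(path)
        self._shape = None

    def __len__(self) -> int:
        return len(self._files)

    def __getitem__(self, i: int) -> np.ndarray:
        frame = iio.imread(self._files[i])
        if frame.ndim != 2:
            raise FormatError(f"{self._files[i]} is not single-channel grayscale")
        if frame.dtype not in (np.dtype("uint8"), np.dtype("uint16")):
            raise FormatError(f"unsupported bit depth: {frame.dtype}")
        if self._shape is None:
            self._shape = frame.shape
        elif frame.shape != self._shape:
            raise FormatError("mixed frame dimensions in image directory")
        return frame


class _RawSequence(FrameSequence):
    def __init__(self, path: Path, config: ImagingConfig | None):
        self._path = path
        with open(path, "rb") as fh:
            header = fh.read(_RAW_HEADER.size)
        if len(header) < _RAW_HEADER.size:
            raise FormatError("raw stream file too short for header")
        magic, w, h, depth, count, rate = _RAW_HEADER.unpack(header)
        if magic != _RAW_MAGIC:
            raise FormatError("not a vdcyto raw stream (bad magic)")
        if depth not in (8, 16):
            raise FormatError(f"unsupported bit depth: {depth}")
        self._w, self._h, self._depth, self._n = w, h, depth, count
        self.frame_rate_hz = rate
        self._dtype = np.uint8 if depth == 8 else np.uint16
        self._frame_bytes = w * h * (depth // 8)
        self.config = config
        self.source = str(path)

    def __len__(self) -> int:
        return self._n

    def __getitem__(self, i: int) -> np.ndarray:
        if not 0 <= i < self._n:
            raise IndexError(i)
        with open(self._path, "rb") as fh:
            fh.seek(_RAW_HEADER.size + i * self._frame_bytes)
            buf = fh.read(self._frame_bytes)
        if len(buf) < self._frame_bytes:
            raise FormatError("raw stream truncated")
        return np.frombuffer(buf, dtype="<" + self._dtype().dtype.char).reshape(
            self._h, self._w
        ).astype(self._dtype)


def open_sequence(path, config: ImagingConfig | None = None) -> FrameSequence:
    """Open a frame container (TIFF stack, image directory, or raw stream).

    When ``config`` supplies ROI dimensions, the first frame is validated
    against them.
    """
    path = Path(path)
    if path.is_dir():
        seq: FrameSequence = _DirSequence(path, config)
    elif path.suffix.lower() in (".tif", ".tiff"):
        seq = _TiffSequence(path, config)
    elif path.suffix.lower() in (".raw", ".vdcs"):
        seq = _RawSequence(path, config)
    else:
        with open(path, "rb") as fh:
            magic = fh.read(4)
        if magic == _RAW_MAGIC:
            seq = _RawSequence(path, config)
        else:
            seq = _TiffSequence(path, config)
    if config is not None and len(seq):
        h, w = seq[0].shape
        if (h, w) != (config.roi_height_px, config.roi_width_px):
            raise FormatError(
                f"frame shape {(h, w)} does not match config ROI "
                f"{(config.roi_height_px, config.roi_width_px)}"
            )
    return seq


def write_frames(path, frames, config: ImagingConfig | None = None) -> None:
    """Write frames to TIFF, a PNG directory, or the raw stream format."""
    path = Path(path)
    frames = np.asarray(frames) if not isinstance(frames, FrameSequence) else frames
    get = (lambda i: frames[i])
    n = len(frames)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffWriter(str(path)) as tw:
            for i in range(n):
                tw.write(get(i), contiguous=False)
    elif path.suffix.lower() in (".raw", ".vdcs"):
        first = np.asarray(get(0))
        depth = 8 if first.dtype == np.uint8 else 16
        rate = config.frame_rate_hz if config else 0.0
        with open(path, "wb") as fh:
            fh.write(
                _RAW_HEADER.pack(_RAW_MAGIC, first.shape[1], first.shape[0], depth, n, rate)
            )
            for i in range(n):
                fh.write(np.ascontiguousarray(get(i)).astype("<" + first.dtype.char).tobytes())
    else:
        path.mkdir(parents=True, exist_ok=True)
        digits = max(4, len(str(n - 1)))
        for i in range(n):
            iio.imwrite(path / f"{i:0{digits}d}.png", np.asarray(get(i)))


# ---------------------------------------------------------------------------
# results tables

SCHEMA_VERSION = 1

RESULTS_COLUMNS = [
    "frame_index",
    "channel_id",
    "centroid_x_um",
    "centroid_y_um",
    "area_um2",
    "perimeter_um",
    "deformability",
    "brightness",
    "aspect_ratio",
    "area_ratio",
    "accepted",
    "reject_reason",
]

_HEADER_LINE = f"# vdcyto-results v{SCHEMA_VERSION}"


def empty_results() -> pd.DataFrame:
    """Header-only results table with the fixed column schema."""
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        RESULTS_COLUMNS,
        [int, int, float, float, float, float, float, float, float, float, bool, str],
    )})
    return df


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as schema-stamped CSV (12 significant digits)."""
    missing = [c for c in RESULTS_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"results table missing columns: {missing}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_HEADER_LINE + "\n")
        table.to_csv(fh, index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    """Read a schema-stamped results CSV, validating the version line."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("# vdcyto-results v"):
            raise SchemaError(f"missing schema header in {path}")
        version = first.rsplit("v", 1)[-1]
        if version != str(SCHEMA_VERSION):
            raise SchemaError(f"unsupported results schema version {version!r}")
        df = pd.read_csv(fh)
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"results table missing columns: {missing}")
    if len(df):
        df["reject_reason"] = df["reject_reason"].fillna("")
    else:
        df = empty_results()
    return df


# ---------------------------------------------------------------------------
# JSON configs and manifests


def config_to_json(config, path=None) -> str:
    """Serialize an ImagingConfig (or any config dataclass) to JSON."""
    payload = {"type": type(config).__name__, **dataclasses.asdict(config)}
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def config_from_json(source) -> ImagingConfig | PopulationSpec:
    """Load an ImagingConfig or PopulationSpec from a JSON file or string."""
    p = Path(str(source))
    text = p.read_text(encoding="utf-8") if p.exists() else str(source)
    payload = json.loads(text)
    kind = payload.pop("type", "ImagingConfig")
    if kind == "PopulationSpec":
        return PopulationSpec(**payload)
    if kind == "ImagingConfig":
        if payload.get("channel_centers_px") is not None:
            payload["channel_centers_px"] = tuple(payload["channel_centers_px"])
        return ImagingConfig(**payload)
    raise FormatError(f"unknown config type {kind!r}")


def _truth_to_dict(cell: SyntheticTruth, include_polygons: bool) -> dict:
    d = {
        "area_true": cell.area_true,
        "perimeter_true": cell.perimeter_true,
        "deformability_true": cell.deformability_true,
        "centroid_true": list(cell.centroid_true),
        "velocity": cell.velocity,
        "channel_id": cell.channel_id,
        "frame_index": cell.frame_index,
        "population": cell.population,
        "border_clipped": cell.border_clipped,
    }
    if include_polygons:
        d["polygon"] = np.asarray(cell.polygon).tolist()
    return d


def manifest_to_json(manifest: TruthManifest, path=None, include_polygons: bool = False) -> str:
    """Serialize a truth manifest (polygons optional: they dominate file size)."""
    payload = {
        "seed": manifest.seed,
        "weights": list(manifest.weights),
        "specs": [{"type": "PopulationSpec", **dataclasses.asdict(s)} for s in manifest.specs],
        "config": json.loads(config_to_json(manifest.config)),
        "warnings": list(manifest.warnings),
        "cells": [_truth_to_dict(c, include_polygons) for c in manifest.cells],
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
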