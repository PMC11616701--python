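"""Staged real-time processing emulation with a bounded frame buffer.

Mirrors the acquisition architecture of a real-time deformability cytometer:
an acquisition stage deposits frames into a bounded FIFO buffer, an analysis
stage drains it running the detection pipeline per frame, and an accumulation
stage maintains the live (area, deformability) scatter density.  The
acquisition stage runs on its own thread; with the ``block`` overflow policy
results are identical to batch processing, while ``drop-oldest`` discards the
oldest unprocessed frame under back-pressure and counts it.

Throughput numbers in :class:`StreamMetrics` are reported, never asserted:
they depend on the host.
"""

from __future__ import annotations

import threading
import time
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import (
    Background,
    DetectionConfig,
    FrameRejected,
    _tally,
    estimate_background,
    process_frame,
)
from .gating import DensityGrid
from .io_formats import RESULTS_COLUMNS, empty_results
from .synth import ImagingConfig

__all__ = ["StreamMetrics", "LiveDensity", "run_stream"]


@dataclass
class StreamMetrics:
    """Counters and rates of one streaming run.

    Invariant: ``frames_in == frames_processed + frames_dropped``.
    """

    frames_in: int = 0
    frames_processed: int = 0
    frames_dropped: int = 0
    cells_detected: int = 0
    wall_time_s: float = 0.0
    achieved_frames_per_s: float = 0.0
    achieved_cells_per_s: float = 0.0
    buffer_high_watermark: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class _BoundedBuffer:
    """FIFO hand-off between acquisition and analysis stages."""

    def __init__(self, capacity: int, drop_policy: str):
        if capacity < 1:
            raise ValueError("buffer_capacity must be >= 1")
        if drop_policy not in ("block", "drop-oldest"):
            raise ValueError("drop_policy must be 'block' or 'drop-oldest'")
        self.capacity = capacity
        self.drop_policy = drop_policy
        self._q: deque = deque()
        self._lock = threading.Lock()
        self._not_full = threading.Condition(self._lock)
        self._not_empty = threading.Condition(self._lock)
        self.dropped = 0
        self.high_watermark = 0
        self._closed = False

    def put(self, item) -> None:
        with self._lock:
            if self.drop_policy == "block":
                while len(self._q) >= self.capacity:
                    self._not_full.wait()
            elif len(self._q) >= self.capacity:
                self._q.popleft()
                self.dropped += 1
            self._q.append(item)
            self.high_watermark = max(self.high_watermark, len(self._q))
            self._not_empty.notify()

    def close(self) -> None:
        with self._lock:
            self._closed = True
            self._not_empty.notify_all()

    def get(self):
        """Next item, or None once the producer closed and the queue drained."""
        with self._lock:
            while not self._q and not self._closed:
                self._not_empty.wait()
            if not self._q:
                return None
            item = self._q.popleft()
            self._not_full.notify()
            return item


class LiveDensity:
    """Incremental (area, deformability) histogram accumulator.

    The grid is fixed up front; points outside the range are clamped to the
    edge bins and counted in ``out_of_range``.  After N single updates the
    normalized grid equals the batch histogram density of the same in-range
    points.
    """

    def __init__(self, x_edges: np.ndarray, y_edges: np.ndarray):
        self.x_edges = np.asarray(x_edges, dtype=float)
        self.y_edges = np.asarray(y_edges, dtype=float)
        self.counts = np.zeros((len(self.x_edges) - 1, len(self.y_edges) - 1))
        self.out_of_range = 0
        self.n = 0

    def update(self, area_um2: float, deformability: float) -> None:
        ix = int(np.searchsorted(self.x_edges, area_um2, side="right")) - 1
        iy = int(np.searchsorted(self.y_edges, deformability, side="right")) - 1
        nx, ny = self.counts.shape
        if not (0 <= ix < nx) or not (0 <= iy < ny):
            # histogram convention: the top edge belongs to the last bin
            if area_um2 == self.x_edges[-1]:
                ix = nx - 1
            if deformability == self.y_edges[-1]:
                iy = ny - 1
            if not (0 <= ix < nx) or not (0 <= iy < ny):
                self.out_of_range += 1
                ix = min(max(ix, 0), nx - 1)
                iy = min(max(iy, 0), ny - 1)
        self.counts[ix, iy] += 1
        self.n += 1

    def grid(self) -> DensityGrid:
        area_per_bin = np.diff(self.x_edges)[:, None] * np.diff(self.y_edges)[None, :]
        total = self.counts.sum()
        dens = self.counts / (total * area_per_bin) if total else self.counts.copy()
        return DensityGrid(dens, self.x_edges, self.y_edges, "histogram", self.n)


def run_stream(
    source,
    config: DetectionConfig | None = None,
    imaging: ImagingConfig | None = None,
    background: Background | None = None,
    buffer_capacity: int = 64,
    drop_policy: str = "block",
    density: LiveDensity | None = None,
    analysis_delay_s: float = 0.0,
) -> tuple[pd.DataFrame, StreamMetrics]:
    """Process a frame source through the staged streaming architecture.

    ``source`` is any indexable frame sequence or iterable of frames.  With
    ``drop_policy="block"`` and no drops the returned table is identical to
    :func:`~vdcyto.detection.process_sequence`.  ``analysis_delay_s`` slows
    the analysis stage artificially (used to exercise back-pressure).
    Analysis exceptions are logged per frame and never abort the stream.
    """
    config = config or DetectionConfig()
    if imaging is None:
        imaging = getattr(source, "config", None) or ImagingConfig()
    metrics = StreamMetrics()
    counters: dict[str, int] = {
        "frames": 0,
        "frames_rejected": 0,
        "candidates": 0,
        "accepted": 0,
    }

    frames_iter = (
        (source[i] for i in range(len(source))) if hasattr(source, "__getitem__") else iter(source)
    )
    if background is None:
        if hasattr(source, "__getitem__") and len(source):
            background = estimate_background(source, n_sample=config.background_frames)
        else:
            raise ValueError("a Background model is required for generator sources")

    buffer = _BoundedBuffer(buffer_capacity, drop_policy)

    def _acquire() -> None:
        for frame in frames_iter:
            metrics.frames_in += 1
            buffer.put((metrics.frames_in - 1, np.asarray(frame)))
        buffer.close()

    producer = threading.Thread(target=_acquire, name="vdcyto-acquisition", daemon=True)
    t0 = time.perf_counter()
    producer.start()

    rows: list[dict] = []
    while True:
        item = buffer.get()
        if item is None:
            break
        index, frame = item
        if analysis_delay_s > 0:
            time.sleep(analysis_delay_s)
        counters["frames"] += 1
        try:
            records = process_frame(frame, index, background, config, imaging)
        except FrameRejected as exc:
            counters["frames_rejected"] += 1
            counters[f"reject_frame_{exc.reason}"] = (
                counters.get(f"reject_frame_{exc.reason}", 0) + 1
            )
            metrics.frames_processed += 1
            continue
        _tally(counters, records)
        for rec in records:
            rows.append(rec.as_row())
            if rec.accepted:
                metrics.cells_detected += 1
                if density is not None:
                    density.update(rec.area_um2, rec.deformability)
        metrics.frames_processed += 1

    producer.join()
    metrics.frames_dropped = buffer.dropped
    metrics.buffer_high_watermark = buffer.high_watermark
    metrics.wall_time_s = time.perf_counter() - t0
    if metrics.wall_time_s > 0:
        metrics.achieved_frames_per_s = metrics.frames_processed / metrics.wall_time_s
        metrics.achieved_cells_per_s = metrics.cells_detected / metrics.wall_time_s

    table = pd.DataFrame(rows, columns=RESULTS_COLUMNS) if rows else empty_results()
    table.attrs["counters"] = counters
    table.attrs["stream_metrics"] = metrics.as_dict()
    return table, metrics
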