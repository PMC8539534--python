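"""Characteristic and peak temperature maps from IR frame bursts.

Each acquisition step contributes a short burst of IR frames; the burst is
collapsed to one characteristic map by frame averaging, warped into the
reference frame, and the per-pixel running maximum across steps forms the
peak-temperature supervision signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TemperatureMap


@dataclass
class PeakTemperatureMap:
    """Per-pixel maximum temperature reached up to acquisition step ``step``.

    ``valid`` marks pixels with full aligned coverage over the whole prefix of
    steps; peak values outside it would be computed from partial data and are
    therefore not trusted.
    """

    data: np.ndarray
    step: int
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.shape != self.valid.shape:
            raise ValueError("peak map and validity mask shapes differ")


def average_frames(frames: list[TemperatureMap], k: int | None = None) -> TemperatureMap:
    """Element-wise mean of the last *k* frames of a burst.

    With ``k=None`` all frames are used.  The characteristic map's timestamp
    is the mean timestamp of the averaged frames.
    """
    if not frames:
        raise ValueError("need at least one frame")
    shape = frames[0].data.shape
    for f in frames:
        if f.data.shape != shape:
            raise ValueError(f"frame shape {f.data.shape} != {shape}")
    chosen = frames if k is None else frames[-k:]
    stack = np.stack([f.data for f in chosen], axis=0)
    ts = float(np.mean([f.timestamp for f in chosen]))
    return TemperatureMap(stack.mean(axis=0), timestamp=ts)


def build_peak_maps(
    aligned_steps: list,
    coverage: list[np.ndarray] | None = None,
) -> list[PeakTemperatureMap]:
    """Running per-pixel maxima over aligned per-step temperature maps.

    ``peak[i] = max(aligned_steps[0..i])`` element-wise.  Steps may be
    :class:`~hsablate.io.TemperatureMap` objects or plain 2-D arrays; warped
    maps may use NaN outside their aligned coverage.  A pixel is valid at
    step i only if it had aligned coverage at *every* step 1..i (a maximum
    over partial data would silently bias the supervision).
    """
    if not aligned_steps:
        raise ValueError("need at least one aligned step map")
    arrays = [
        np.asarray(t.data if isinstance(t, TemperatureMap) else t, dtype=np.float64)
        for t in aligned_steps
    ]
    shape = arrays[0].shape
    if coverage is None:
        coverage = [np.isfinite(a) for a in arrays]
    peaks: list[PeakTemperatureMap] = []
    running = np.full(shape, -np.inf, dtype=np.float64)
    valid = np.ones(shape, dtype=bool)
    for i, (arr, cov) in enumerate(zip(arrays, coverage, strict=True), start=1):
        if arr.shape != shape:
            raise ValueError("all step maps must share the reference-frame shape")
        valid &= np.asarray(cov, dtype=bool)
        data = np.where(np.isfinite(arr), arr, -np.inf)
        running = np.maximum(running, data)
        out = np.where(valid, running, np.nan).astype(np.float32)
        peaks.append(PeakTemperatureMap(out, step=i, valid=valid.copy()))
    return peaks
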