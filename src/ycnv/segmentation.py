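"""Threshold-run-merge segmentation of MSY log2-ratio profiles.

Per-probe copy states are called against thresholds placed at the midpoints
of the three empirical state means (loss below -1.245, gain above -0.215
under defaults), runs of a single non-normal state are merged across short
discordant gaps, and candidate segments must satisfy a minimum marker count
(3), a minimum genomic size (5 kb) and a minimum probe density.  The
density filter automates the removal of spurious calls in probe-poor
regions that would otherwise require manual curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .defaults import MU_ONE_COPY, MU_TWO_COPY, MU_ZERO_COPY
from .probe_map import ProbeManifest

__all__ = ["Segment", "SegmentationParams", "call_states", "segment", "density_filter", "segments_to_frame"]

logger = logging.getLogger(__name__)

LOSS, NORMAL, GAIN = -1, 0, 1
_STATE_NAMES = {LOSS: "loss", GAIN: "gain"}


@dataclass(frozen=True)
class SegmentationParams:
    """Caller settings; thresholds default to state-mean midpoints.

    ``smooth_window`` is the odd width of the centered moving average the
    profile is passed through before thresholding (1 disables smoothing).
    Local averaging is the caller's evidence unit: it shrinks per-probe
    noise by sqrt(window) while leaving state transitions of at least
    ceil(window/2) probes at their exact boundaries in the noise-free
    limit.
    """

    min_markers: int = 3
    min_size_kb: float = 5.0
    loss_threshold: float = (MU_ZERO_COPY + MU_ONE_COPY) / 2.0  # -1.245
    gain_threshold: float = (MU_ONE_COPY + MU_TWO_COPY) / 2.0  # -0.215
    max_gap: int = 1
    min_density: float = 0.05  # probes per kb
    smooth_window: int = 5

    def __post_init__(self) -> None:
        if self.min_markers < 1:
            raise ValueError("min_markers must be >= 1")
        if self.loss_threshold >= self.gain_threshold:
            raise ValueError("loss_threshold must be below gain_threshold")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 1")


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; windows shrink symmetrically at the ends."""
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window == 1 or len(values) <= 1:
        return values.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


@dataclass(frozen=True)
class Segment:
    """A called loss/gain segment over contiguous manifest probes."""

    state: str  # "loss" | "gain"
    first_index: int
    last_index: int
    start: int
    stop: int
    n_markers: int
    mean_log2: float

    @property
    def span(self) -> int:
        """Genomic size in bp (1-based closed interval)."""
        return self.stop - self.start + 1

    @property
    def density(self) -> float:
        """Probes per kb over the segment span."""
        return self.n_markers / (self.span / 1000.0)


def call_states(
    profile: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Per-probe state in {-1 loss, 0 normal, +1 gain}.

    The profile is first passed through the params' centered moving
    average (a constant profile is unchanged); smoothed values exactly at
    a threshold are called normal.
    """
    params = params or SegmentationParams()
    values = moving_average(np.asarray(profile, dtype=float), params.smooth_window)
    states = np.zeros(len(values), dtype=np.int8)
    # tiny guard keeps exact threshold ties "normal" despite the smoothing
    # cumsum's float error
    eps = 1e-9
    states[values < params.loss_threshold - eps] = LOSS
    states[values > params.gain_threshold + eps] = GAIN
    return states


def _runs_for_state(states: np.ndarray, target: int, max_gap: int) -> list[tuple[int, int]]:
    """Maximal (first, last) index runs of ``target`` allowing interior
    discordant gaps of at most ``max_gap`` probes.  Run endpoints are always
    concordant probes."""
    idx = np.flatnonzero(states == target)
    if idx.size == 0:
        return []
    runs = []
    first = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= max_gap:
            prev = i
        else:
            runs.append((int(first), int(prev)))
            first = prev = i
    runs.append((int(first), int(prev)))
    return runs


def segment(
    states: np.ndarray,
    manifest: ProbeManifest,
    profile: np.ndarray,
    params: SegmentationParams | None = None,
) -> list[Segment]:
    """Merge per-probe states into loss/gain segments.

    Runs failing ``min_markers`` or ``min_size_kb`` are dropped; the
    surviving segments are sorted by start position.  ``n_markers`` counts
    every probe inside the segment extent (including tolerated discordant
    probes) and ``mean_log2`` averages over the same probes.
    """
    params = params or SegmentationParams()
    states = np.asarray(states)
    if len(states) != len(manifest):
        raise ValueError("states not aligned to manifest")
    values = np.asarray(profile, dtype=float)
    segments: list[Segment] = []
    for target in (LOSS, GAIN):
        for first, last in _runs_for_state(states, target, params.max_gap):
            n_markers = last - first + 1
            start = int(manifest.positions[first])
            stop = int(manifest.positions[last])
            if n_markers < params.min_markers:
                continue
            if (stop - start + 1) < params.min_size_kb * 1000.0:
                continue
            segments.append(
                Segment(
                    state=_STATE_NAMES[target],
                    first_index=first,
                    last_index=last,
                    start=start,
                    stop=stop,
                    n_markers=n_markers,
                    mean_log2=float(values[first : last + 1].mean()),
                )
            )
    segments.sort(key=lambda s: (s.start, s.stop, s.state))
    return segments


def density_filter(
    segments: list[Segment],
    min_density: float = SegmentationParams.min_density,
) -> list[Segment]:
    """Drop segments with fewer than ``min_density`` probes per kb.

    Automates the curation of spurious calls spanning probe-poor sequence;
    removals are logged with their density.
    """
    if min_density <= 0:
        raise ValueError("min_density must be > 0")
    kept = []
    for seg in segments:
        if seg.density < min_density:
            logger.info(
                "density filter removed %s segment %d-%d (%.4f probes/kb < %.4f)",
                seg.state, seg.start, seg.stop, seg.density, min_density,
            )
        else:
            kept.append(seg)
    return kept


def segments_to_frame(segments: list[Segment], sample: str = "") -> pd.DataFrame:
    """Tabulate segments (1-based closed coordinates)."""
    return pd.DataFrame(
        [
            {
                "sample": sample,
                "state": s.state,
                "start": s.start,
                "stop": s.stop,
                "n_markers": s.n_markers,
                "span_bp": s.span,
                "mean_log2": s.mean_log2,
            }
            for s in segments
        ],
        columns=["sample", "state", "start", "stop", "n_markers", "span_bp", "mean_log2"],
    )
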