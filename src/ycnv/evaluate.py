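"""Recovery metrics for benchmarking the caller against generator truth."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .probe_map import ProbeManifest
from .segmentation import Segment
from .synthetic import CNVEvent

__all__ = ["event_probe_range", "event_recovered"]

_KIND_TO_STATE = {"deletion": "loss", "duplication": "gain"}


def event_probe_range(event: CNVEvent, manifest: ProbeManifest) -> tuple[int, int]:
    """(first, last) manifest probe indices covered by an event."""
    lo = int(np.searchsorted(manifest.positions, event.start, side="left"))
    hi = int(np.searchsorted(manifest.positions, event.stop, side="right")) - 1
    if hi < lo:
        raise ValueError("event covers no probes")
    return lo, hi


def event_recovered(
    event: CNVEvent,
    segments: Sequence[Segment],
    manifest: ProbeManifest,
    tol_probes: int = 2,
) -> bool:
    """True if the called segments recover the event's extent.

    The envelope of all same-state segments overlapping the event (what the
    region-state step consumes) must place both breakpoints within
    ``tol_probes`` probes of the truth.
    """
    lo, hi = event_probe_range(event, manifest)
    state = _KIND_TO_STATE[event.kind]
    overlapping = [
        s
        for s in segments
        if s.state == state and s.first_index <= hi and s.last_index >= lo
    ]
    if not overlapping:
        return False
    env_first = min(s.first_index for s in overlapping)
    env_last = max(s.last_index for s in overlapping)
    return abs(env_first - lo) <= tol_probes and abs(env_last - hi) <= tol_probes
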