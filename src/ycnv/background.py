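"""Window-averaged intensity summaries, sex inference and the female
high-background probe blacklist.

On the haploid MSY, male single-copy probes average about -0.47 (log2
ratio) and female background about -2.02.  A handful of regions
cross-hybridise in females and rise towards male intensity; probes in
3-probe windows whose across-female mean exceeds a threshold are excluded
from CNV calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .defaults import MU_ONE_COPY, MU_ZERO_COPY
from .probe_map import ProbeManifest

__all__ = ["WindowSummary", "ProbeBlacklist", "window_means", "flag_high_background", "infer_sex"]

SEX_MIDPOINT = (MU_ONE_COPY + MU_ZERO_COPY) / 2.0  # -1.245 under defaults


@dataclass(frozen=True)
class WindowSummary:
    """Disjoint consecutive window means over a profile in manifest order."""

    size: int
    means: np.ndarray
    # [start, stop) probe-index range per window
    index_ranges: np.ndarray
    has_short_tail: bool

    @property
    def n_windows(self) -> int:
        return len(self.means)


@dataclass(frozen=True)
class ProbeBlacklist:
    """Probes excluded from CNV calling for high female background."""

    probe_ids: frozenset[str]
    evidence: pd.DataFrame  # probe_id, female_window_mean, male_mean, reason

    def __len__(self) -> int:
        return len(self.probe_ids)

    def mask(self, manifest: ProbeManifest) -> np.ndarray:
        """Boolean keep-mask over manifest probes (True = keep)."""
        return np.array(
            [pid not in self.probe_ids for pid in manifest.probe_ids], dtype=bool
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# probes excluded from CNV calling\n")
            self.evidence.to_csv(fh, sep="\t", index=False)


def window_means(profile: np.ndarray, size: int) -> WindowSummary:
    """Means of disjoint blocks of ``size`` consecutive probes.

    A trailing remainder shorter than ``size`` is reported as a final short
    window and flagged via ``has_short_tail``.
    """
    if size < 1:
        raise ValueError(f"window size must be >= 1, got {size}")
    values = np.asarray(profile, dtype=float)
    n = len(values)
    n_full = n // size
    means = []
    ranges = []
    for w in range(n_full):
        means.append(values[w * size : (w + 1) * size].mean())
        ranges.append((w * size, (w + 1) * size))
    tail = n - n_full * size
    if tail:
        means.append(values[n_full * size :].mean())
        ranges.append((n_full * size, n))
    return WindowSummary(
        size=size,
        means=np.array(means),
        index_ranges=np.array(ranges, dtype=np.intp),
        has_short_tail=bool(tail),
    )


def flag_high_background(
    female_profiles: np.ndarray,
    male_profiles: np.ndarray | None,
    manifest: ProbeManifest,
    window: int = 3,
    threshold: float = MU_ONE_COPY,
) -> ProbeBlacklist:
    """Blacklist probes whose ``window``-probe across-female mean exceeds
    ``threshold``.

    ``female_profiles`` (and optionally ``male_profiles``, used only as
    reported evidence) are (n_samples, n_probes) arrays aligned to the
    manifest.  The default threshold is the male single-copy mean: windows
    where females look as bright as males carry no copy-number information.
    """
    females = np.atleast_2d(np.asarray(female_profiles, dtype=float))
    if females.shape[0] < 1:
        raise ValueError("at least one female profile is required")
    if females.shape[1] != len(manifest):
        raise ValueError(
            f"female profiles have {females.shape[1]} probes, manifest has {len(manifest)}"
        )
    male_mean = None
    if male_profiles is not None and len(male_profiles):
        males = np.atleast_2d(np.asarray(male_profiles, dtype=float))
        if males.shape[1] != females.shape[1]:
            raise ValueError("male and female profiles have mismatched probe counts")
        male_mean = males.mean(axis=0)

    per_probe_female = females.mean(axis=0)
    summary = window_means(per_probe_female, window)
    rows = []
    bad_ids: set[str] = set()
    for mean, (lo, hi) in zip(summary.means, summary.index_ranges):
        if mean > threshold:
            for i in range(lo, hi):
                pid = manifest.probe_ids[i]
                bad_ids.add(pid)
                rows.append(
                    {
                        "probe_id": pid,
                        "position": int(manifest.positions[i]),
                        "female_window_mean": float(mean),
                        "male_mean": float(male_mean[i]) if male_mean is not None else np.nan,
                        "reason": f"female {window}-probe window mean {mean:.3f} > {threshold}",
                    }
                )
    evidence = pd.DataFrame(
        rows,
        columns=["probe_id", "position", "female_window_mean", "male_mean", "reason"],
    )
    return ProbeBlacklist(probe_ids=frozenset(bad_ids), evidence=evidence)


def infer_sex(profile: np.ndarray, midpoint: float = SEX_MIDPOINT) -> str:
    """Classify a sample as male or female from its mean MSY log2 ratio.

    Male iff the mean lies at or above the midpoint of the one-copy and
    zero-copy state means (ties resolve to male; they have probability zero
    under the continuous intensity model).
    """
    values = np.asarray(profile, dtype=float)
    if values.size == 0:
        raise ValueError("cannot infer sex from an empty profile")
    return "male" if values.mean() >= midpoint - 1e-12 else "female"
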