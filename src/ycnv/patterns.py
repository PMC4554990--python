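"""Region copy states and classification against the named CNV-pattern
catalog.

Segments are reduced to a per-region copy state (deleted / normal /
duplicated / partial, or "no-probe" for uncovered amplicons) by the
fraction of each region's probes that called segments cover.  The state
vector is then matched greedily against a catalog of named signatures;
region combinations absent from the catalog are reported as novel rather
than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml

from .probe_map import ProbeAnnotation, ProbeManifest, RegionDef
from .segmentation import Segment

__all__ = [
    "CopyStateVector",
    "PatternSignature",
    "PatternCall",
    "region_copy_states",
    "classify",
    "load_catalog",
]

DELETED, DUPLICATED, NORMAL, PARTIAL, NO_PROBE = (
    "deleted",
    "duplicated",
    "normal",
    "partial",
    "no-probe",
)
# States that demand explanation by a signature (partial evidence and
# probe-free regions do not).
_NON_NORMAL = (DELETED, DUPLICATED)


@dataclass(frozen=True)
class CopyStateVector:
    """Per-region copy state with the supporting probe fraction."""

    states: dict[str, str]
    fractions: dict[str, float]

    def __getitem__(self, region: str) -> str:
        return self.states[region]

    @property
    def non_normal(self) -> dict[str, str]:
        return {r: s for r, s in self.states.items() if s in _NON_NORMAL}


@dataclass(frozen=True)
class PatternSignature:
    """A named CNV signature: required region -> state; others wildcard."""

    name: str
    requires: dict[str, str]

    def satisfied_by(self, vector: CopyStateVector) -> bool:
        return all(
            vector.states.get(region) == state
            for region, state in self.requires.items()
        )


@dataclass(frozen=True)
class PatternCall:
    """A matched catalog signature, or a novel-signature record."""

    pattern: str  # signature name, or "novel"
    regions: tuple[str, ...]
    novel: bool
    signature_string: str


def signature_string(states: Mapping[str, str], regions: Sequence[RegionDef]) -> str:
    """Canonical genomic-order rendering, e.g. ``U3:deleted+b3:deleted``."""
    order = {r.name: r.start for r in regions}
    items = sorted(states.items(), key=lambda kv: (order.get(kv[0], 0), kv[0]))
    return "+".join(f"{r}:{s}" for r, s in items)


def region_copy_states(
    segments: Sequence[Segment],
    annotation: ProbeAnnotation,
    regions: Sequence[RegionDef],
    coverage_threshold: float = 0.8,
    manifest: ProbeManifest | None = None,
) -> CopyStateVector:
    """Reduce called segments to one copy state per annotated region.

    A region is deleted/duplicated iff at least ``coverage_threshold`` of
    its probes lie inside loss/gain segment extents; non-zero sub-threshold
    coverage yields ``partial``; regions with no probes yield ``no-probe``
    and are never matched by the classifier.
    """
    if not (0 < coverage_threshold <= 1):
        raise ValueError("coverage_threshold must be in (0, 1]")
    states: dict[str, str] = {}
    fractions: dict[str, float] = {}
    loss_iv = [(s.first_index, s.last_index) for s in segments if s.state == "loss"]
    gain_iv = [(s.first_index, s.last_index) for s in segments if s.state == "gain"]
    for region in regions:
        idx = annotation.probes_in(region.name)
        if idx.size == 0:
            states[region.name] = NO_PROBE
            fractions[region.name] = 0.0
            continue
        in_loss = np.zeros(idx.shape, dtype=bool)
        for lo, hi in loss_iv:
            in_loss |= (idx >= lo) & (idx <= hi)
        in_gain = np.zeros(idx.shape, dtype=bool)
        for lo, hi in gain_iv:
            in_gain |= (idx >= lo) & (idx <= hi)
        frac_loss = float(in_loss.mean())
        frac_gain = float(in_gain.mean())
        if frac_loss >= coverage_threshold:
            states[region.name] = DELETED
            fractions[region.name] = frac_loss
        elif frac_gain >= coverage_threshold:
            states[region.name] = DUPLICATED
            fractions[region.name] = frac_gain
        elif frac_loss + frac_gain > 0:
            states[region.name] = PARTIAL
            fractions[region.name] = frac_loss + frac_gain
        else:
            states[region.name] = NORMAL
            fractions[region.name] = 0.0
    return CopyStateVector(states=states, fractions=fractions)


def classify(
    vector: CopyStateVector,
    catalog: Sequence[PatternSignature],
    regions: Sequence[RegionDef] = (),
) -> list[PatternCall]:
    """Match a copy-state vector against the catalog.

    Greedy cover: among signatures whose requirements the vector satisfies
    and which still explain at least one unexplained non-normal region, the
    one with the most required regions wins (ties broken lexicographically
    by name); matching repeats on the remaining regions, so a sample may
    carry several independent patterns.  Regions left unexplained form a
    single novel-signature call.  An all-normal vector yields no calls.
    """
    if not catalog:
        raise ValueError("empty pattern catalog")
    remaining = dict(vector.non_normal)
    if not remaining:
        return []
    satisfied = [sig for sig in catalog if sig.satisfied_by(vector)]
    calls: list[PatternCall] = []
    while remaining:
        best = None
        for sig in satisfied:
            if not any(r in remaining for r in sig.requires):
                continue
            key = (len(sig.requires), sig.name)
            if best is None or (len(best.requires), best.name) < key:
                best = sig
        if best is None:
            break
        calls.append(
            PatternCall(
                pattern=best.name,
                regions=tuple(sorted(best.requires)),
                novel=False,
                signature_string=signature_string(best.requires, regions),
            )
        )
        for r in best.requires:
            remaining.pop(r, None)
        satisfied.remove(best)
    if remaining:
        calls.append(
            PatternCall(
                pattern="novel",
                regions=tuple(sorted(remaining)),
                novel=True,
                signature_string=signature_string(remaining, regions),
            )
        )
    return calls


def load_catalog(
    path, regions: Sequence[RegionDef] | None = None
) -> list[PatternSignature]:
    """Load a YAML pattern catalog and validate names and region references."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = raw.get("patterns") if isinstance(raw, dict) else raw
    if not entries:
        raise ValueError(f"{path}: no patterns found")
    known = {r.name for r in regions} if regions is not None else None
    seen: set[str] = set()
    catalog: list[PatternSignature] = []
    for entry in entries:
        name = entry["name"]
        if name in seen:
            raise ValueError(f"duplicate pattern name {name!r} in catalog")
        seen.add(name)
        requires = dict(entry["requires"])
        for region, state in requires.items():
            if state not in _NON_NORMAL:
                raise ValueError(
                    f"pattern {name!r}: state {state!r} must be deleted/duplicated"
                )
            if known is not None and region not in known:
                raise ValueError(
                    f"pattern {name!r} names unknown region {region!r}"
                )
        catalog.append(PatternSignature(name=name, requires=requires))
    return catalog
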