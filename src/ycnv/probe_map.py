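"""Probe manifests, STS-delimited region definitions and probe annotation.

Coordinates throughout are 1-based, fully closed intervals on chrY (UCSC
browser display convention).  A probe belongs to a region iff
``start <= position <= stop``, both ends inclusive; regions may overlap and
a probe may therefore carry several region labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeManifest",
    "RegionDef",
    "ProbeAnnotation",
    "load_manifest",
    "load_sts_table",
    "build_regions",
    "load_region_pairing",
    "assign_probes",
]

PROBE_CLASSES = ("SNP", "CN")
REGION_CLASSES = ("palindrome", "amplicon", "inverted_repeat", "spacer")


@dataclass(frozen=True)
class ProbeManifest:
    """Ordered MSY probe map: ids, 1-based positions and SNP/CN classes."""

    probe_ids: np.ndarray
    positions: np.ndarray
    probe_classes: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.probe_ids, dtype=object)
        pos = np.asarray(self.positions, dtype=np.int64)
        cls = np.asarray(self.probe_classes, dtype=object)
        if not (len(ids) == len(pos) == len(cls)):
            raise ValueError("manifest columns have unequal lengths")
        if len(ids) == 0:
            raise ValueError("empty probe manifest")
        order = np.argsort(pos, kind="stable")
        ids, pos, cls = ids[order], pos[order], cls[order]
        dup = pd.Index(ids).duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate probe_id(s): {sorted(set(ids[dup]))[:5]}"
            )
        bad = set(cls) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe class(es): {sorted(bad)}")
        object.__setattr__(self, "probe_ids", ids)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "probe_classes", cls)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_probes(self) -> int:
        return len(self.positions)

    @property
    def n_snp(self) -> int:
        return int(np.sum(self.probe_classes == "SNP"))

    @property
    def n_cn(self) -> int:
        return int(np.sum(self.probe_classes == "CN"))

    @property
    def span(self) -> tuple[int, int]:
        return int(self.positions[0]), int(self.positions[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "position": self.positions,
                "probe_class": self.probe_classes,
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# probe manifest (chrY, 1-based positions)\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class RegionDef:
    """A named palindrome/amplicon interval delimited by two STS markers."""

    name: str
    start: int
    stop: int
    region_class: str = "amplicon"
    bounding_markers: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if self.start >= self.stop:
            raise ValueError(
                f"region {self.name}: start {self.start} must be < stop {self.stop}"
            )
        if self.region_class not in REGION_CLASSES:
            raise ValueError(
                f"region {self.name}: unknown region_class {self.region_class!r}"
            )

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass
class ProbeAnnotation:
    """Mapping probe_id -> set of region names (empty set = single copy)."""

    assignments: dict[str, frozenset[str]]
    region_probes: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, probe_id: str) -> frozenset[str]:
        return self.assignments[probe_id]

    def __len__(self) -> int:
        return len(self.assignments)

    def probes_in(self, region: str) -> np.ndarray:
        """Indices (manifest order) of probes assigned to ``region``."""
        return self.region_probes.get(region, np.empty(0, dtype=np.intp))


def _read_tsv(path, names: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    return df


def load_manifest(path) -> ProbeManifest:
    """Read a probe manifest TSV (probe_id, position, probe_class).

    Rows are sorted by position; duplicate positions are permitted,
    duplicate ids are rejected.
    """
    df = _read_tsv(path, ("probe_id", "position", "probe_class"))
    try:
        positions = df["position"].astype(np.int64).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric probe position ({exc})") from None
    return ProbeManifest(
        probe_ids=df["probe_id"].to_numpy(dtype=object),
        positions=positions,
        probe_classes=df["probe_class"].str.upper().to_numpy(dtype=object),
    )


def load_sts_table(path) -> pd.DataFrame:
    """Read an STS marker table TSV (name, start, stop), 1-based closed."""
    df = _read_tsv(path, ("name", "start", "stop"))
    df["start"] = df["start"].astype(np.int64)
    df["stop"] = df["stop"].astype(np.int64)
    if (df["start"] > df["stop"]).any():
        bad = df.loc[df["start"] > df["stop"], "name"].tolist()
        raise ValueError(f"STS marker(s) with start > stop: {bad}")
    if df["name"].duplicated().any():
        bad = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate STS marker name(s): {bad}")
    return df.set_index("name")


def load_region_pairing(path) -> list[dict]:
    """Read a region pairing TSV (name, left_marker, right_marker, region_class)."""
    df = _read_tsv(path, ("name", "left_marker", "right_marker", "region_class"))
    return df.to_dict("records")


def build_regions(
    sts_table: pd.DataFrame, pairing_spec: Iterable[Mapping[str, str]]
) -> list[RegionDef]:
    """Construct region definitions from STS markers and a pairing spec.

    Each region spans from its left marker's *start* to its right marker's
    *stop* (marker interiors inclusive).  ``pairing_spec`` items need keys
    ``name``, ``left_marker``, ``right_marker`` and ``region_class``.
    """
    regions: list[RegionDef] = []
    seen: set[str] = set()
    for spec in pairing_spec:
        name = spec["name"]
        if name in seen:
            raise ValueError(f"duplicate region name {name!r} in pairing spec")
        seen.add(name)
        for key in ("left_marker", "right_marker"):
            if spec[key] not in sts_table.index:
                raise ValueError(
                    f"region {name!r}: marker {spec[key]!r} absent from STS table"
                )
        left = sts_table.loc[spec["left_marker"]]
        right = sts_table.loc[spec["right_marker"]]
        regions.append(
            RegionDef(
                name=name,
                start=int(left["start"]),
                stop=int(right["stop"]),
                region_class=spec["region_class"],
                bounding_markers=(spec["left_marker"], spec["right_marker"]),
            )
        )
    return regions


def assign_probes(
    manifest: ProbeManifest, regions: Sequence[RegionDef]
) -> ProbeAnnotation:
    """Assign every manifest probe to the regions whose interval contains it.

    Membership is inclusive at both interval ends; probes outside every
    region map to the empty set.  The result is invariant under permutation
    of the region list.
    """
    pos = manifest.positions
    sets: list[set[str]] = [set() for _ in range(len(pos))]
    region_probes: dict[str, np.ndarray] = {}
    for region in regions:
        lo = int(np.searchsorted(pos, region.start, side="left"))
        hi = int(np.searchsorted(pos, region.stop, side="right"))
        idx = np.arange(lo, hi, dtype=np.intp)
        region_probes[region.name] = idx
        for i in idx:
            sets[i].add(region.name)
    assignments = {
        pid: frozenset(s) for pid, s in zip(manifest.probe_ids, sets)
    }
    return ProbeAnnotation(assignments=assignments, region_probes=region_probes)
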