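"""Synthetic MSY array cohorts: intensity profiles, truth CNV events and
Y-SNP genotypes.

The generator emulates the statistical structure the downstream analysis
assumes: per-probe log2 ratios are normal around state-dependent means
(one-copy male -0.47, zero-copy/female -2.02, two-copy 0.04, s.d. 0.25 by
default), females show elevated background in three fixed intervals, CNV
events are drawn per sample from haplogroup-conditional pattern
frequencies, and genotypes are derived along the root path of the
haplogroup tree.  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .defaults import (
    DESERT_REGIONS,
    HOT_MEAN,
    HOT_REGIONS,
    MAJOR_LABELS,
    MU_ONE_COPY,
    MU_TWO_COPY,
    MU_ZERO_COPY,
    DEFAULT_SIGMA,
    MSY_SPAN,
    REAL_ARRAY_N_PROBES,
    REAL_ARRAY_N_SNP,
)
from .haplogroup import MISSING, YTree
from .patterns import DELETED, DUPLICATED, PatternSignature, load_catalog
from .probe_map import ProbeAnnotation, ProbeManifest, RegionDef, assign_probes

__all__ = [
    "IntensityModel",
    "CNVEvent",
    "CohortConfig",
    "SimulatedCohort",
    "synthetic_manifest",
    "simulate_sample",
    "events_for_signature",
    "simulate_genotypes",
    "default_cohort_config",
    "simulate_cohort",
]

_LABEL_TO_NODE = {label: node for node, label in MAJOR_LABELS.items()}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class IntensityModel:
    """State-dependent intensity means and per-probe noise."""

    mu_one_copy: float = MU_ONE_COPY
    mu_zero_copy: float = MU_ZERO_COPY
    mu_two_copy: float = MU_TWO_COPY
    sigma: float = DEFAULT_SIGMA
    background_hot_regions: tuple[tuple[int, int], ...] = HOT_REGIONS
    hot_mean: float = HOT_MEAN

    def __post_init__(self) -> None:
        if not (self.mu_zero_copy < self.mu_one_copy < self.mu_two_copy):
            raise ValueError("state means must be ordered zero < one < two copy")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def state_mean(self, state: int) -> float:
        return {0: self.mu_zero_copy, 1: self.mu_one_copy, 2: self.mu_two_copy}[state]


@dataclass(frozen=True)
class CNVEvent:
    """A deletion or duplication with 1-based closed genomic bounds."""

    kind: str  # "deletion" | "duplication"
    start: int
    stop: int
    pattern_name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "duplication"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start >= self.stop:
            raise ValueError("event start must be < stop")

    @property
    def target_state(self) -> int:
        return 0 if self.kind == "deletion" else 2


def synthetic_manifest(
    n_probes: int = 2000,
    span: tuple[int, int] = MSY_SPAN,
    regions: Sequence[RegionDef] | None = None,
    desert_regions: frozenset[str] = DESERT_REGIONS,
    dense_regions: Mapping[str, int] | None = None,
    snp_fraction: float = REAL_ARRAY_N_SNP / REAL_ARRAY_N_PROBES,
) -> ProbeManifest:
    """Evenly spaced probe grid over the MSY span.

    Probes falling inside the probe-free amplicons (g1, r1, r2, g4 by
    default) are removed, mirroring the uncovered AZFc amplicons of the
    real array; conversely, regions the real array covers more densely
    than average (``dense_regions``: name -> probe count at real scale)
    are filled to their scaled probe count.  The returned manifest may
    therefore hold slightly more or fewer than ``n_probes`` probes.  Use
    ``n_probes=8179`` for the real-scale mode.
    """
    if regions is None:
        regions = defaults.default_region_map()
    if dense_regions is None:
        dense_regions = defaults.DENSE_REGIONS
    by_name = {r.name: r for r in regions}
    positions = np.linspace(span[0], span[1], n_probes).round().astype(np.int64)
    keep = np.ones(len(positions), dtype=bool)
    for region in regions:
        if region.name in desert_regions:
            keep &= ~((positions >= region.start) & (positions <= region.stop))
    positions = positions[keep]
    for name, real_count in dense_regions.items():
        region = by_name[name]
        target = max(3, round(real_count * n_probes / REAL_ARRAY_N_PROBES))
        inside = (positions >= region.start) & (positions <= region.stop)
        if inside.sum() < target:
            filled = (
                np.linspace(region.start, region.stop, target).round().astype(np.int64)
            )
            positions = np.sort(np.concatenate([positions[~inside], filled]))
    n = len(positions)
    snp_every = max(1, round(1.0 / snp_fraction))
    classes = np.array(
        ["SNP" if i % snp_every == 0 else "CN" for i in range(n)], dtype=object
    )
    ids = np.array(
        [f"{'SNP' if c == 'SNP' else 'CN'}_Y_{p}" for c, p in zip(classes, positions)],
        dtype=object,
    )
    return ProbeManifest(probe_ids=ids, positions=positions, probe_classes=classes)


def _copy_states(
    manifest: ProbeManifest, sex: str, events: Sequence[CNVEvent]
) -> np.ndarray:
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be male or female, got {sex!r}")
    lo, hi = manifest.span
    states = np.full(len(manifest), 1 if sex == "male" else 0, dtype=np.int8)
    for event in events:
        if event.stop < lo or event.start > hi:
            raise ValueError(
                f"event {event.start}-{event.stop} lies outside manifest span {lo}-{hi}"
            )
        mask = (manifest.positions >= event.start) & (manifest.positions <= event.stop)
        states[mask] = event.target_state
    return states


def simulate_sample(
    manifest: ProbeManifest,
    model: IntensityModel = IntensityModel(),
    sex: str = "male",
    events: Sequence[CNVEvent] = (),
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """One per-probe log2-ratio profile.

    Each probe is drawn from a normal law centred on its copy state's mean
    (events override the sex baseline of one copy for males, zero for
    females); zero-copy probes inside the model's hot regions use the
    elevated background mean instead.  Identical inputs and seed give
    identical output.
    """
    rng = _as_rng(seed)
    states = _copy_states(manifest, sex, events)
    means = np.empty(len(manifest), dtype=float)
    for state in (0, 1, 2):
        means[states == state] = model.state_mean(state)
    zero = states == 0
    for lo, hi in model.background_hot_regions:
        in_hot = (manifest.positions >= lo) & (manifest.positions <= hi)
        means[zero & in_hot] = model.hot_mean
    return means + rng.normal(0.0, model.sigma, size=len(manifest))


def events_for_signature(
    signature: PatternSignature | Mapping[str, str],
    annotation: ProbeAnnotation,
    manifest: ProbeManifest,
    jitter_probes: int = 0,
    rng: np.random.Generator | None = None,
    pattern_name: str | None = None,
) -> list[CNVEvent]:
    """Concrete CNV events realising a catalog signature.

    Each required region's probes are set to the signature's target state
    (deletions win the few probes shared by overlapping regions of opposite
    state) and maximal runs of a common non-normal state become events.
    ``jitter_probes`` shifts every event end by up to that many probes,
    emulating the boundary heterogeneity of recurrent duplications, without
    crossing into a neighbouring event.
    """
    if isinstance(signature, PatternSignature):
        requires = signature.requires
        pattern_name = pattern_name or signature.name
    else:
        requires = dict(signature)
    target = np.ones(len(manifest), dtype=np.int8)
    for state_value, state_name in ((2, DUPLICATED), (0, DELETED)):
        for region, state in requires.items():
            if state == state_name:
                idx = annotation.probes_in(region)
                if idx.size == 0:
                    raise ValueError(
                        f"region {region!r} has no probes; cannot realise signature"
                    )
                target[idx] = state_value
    # maximal runs of constant non-normal target state
    runs: list[tuple[int, int, int]] = []
    i = 0
    n = len(target)
    while i < n:
        if target[i] == 1:
            i += 1
            continue
        j = i
        while j + 1 < n and target[j + 1] == target[i]:
            j += 1
        runs.append((i, j, int(target[i])))
        i = j + 1
    events: list[CNVEvent] = []
    rng = _as_rng(rng)
    for k, (first, last, state) in enumerate(runs):
        if jitter_probes:
            low = runs[k - 1][1] + 1 if k else 0
            high = runs[k + 1][0] - 1 if k + 1 < len(runs) else n - 1
            first = int(np.clip(first + rng.integers(-jitter_probes, jitter_probes + 1), low, last))
            last = int(np.clip(last + rng.integers(-jitter_probes, jitter_probes + 1), first, high))
        events.append(
            CNVEvent(
                kind="deletion" if state == 0 else "duplication",
                start=int(manifest.positions[first]),
                stop=int(manifest.positions[last]),
                pattern_name=pattern_name,
            )
        )
    return events


def simulate_genotypes(
    tree: YTree,
    haplogroup: str,
    missing_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> dict[str, str]:
    """Genotype consistent with membership of ``haplogroup``.

    Derived allele at every SNP defining a node on the root path, ancestral
    at every other tree SNP; each call is then independently masked as
    missing with probability ``missing_rate``.
    """
    if haplogroup not in tree:
        raise ValueError(f"unknown tree node {haplogroup!r}")
    if not (0 <= missing_rate <= 1):
        raise ValueError("missing_rate must be in [0, 1]")
    rng = _as_rng(rng)
    path = {node.name for node in tree.path_to_root(haplogroup)}
    genotype: dict[str, str] = {}
    for snp_id, node in tree.snp_to_node.items():
        anc, der = tree.snp_alleles[snp_id]
        allele = der if node.name in path else anc
        if missing_rate and rng.random() < missing_rate:
            allele = MISSING
        genotype[snp_id] = allele
    return genotype


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and generator settings.

    ``haplogroup_counts`` gives males per (major-label) haplogroup;
    ``pattern_probs`` gives each haplogroup's per-pattern carrier
    probabilities (must sum to at most 1; the remainder carries no CNV).
    """

    haplogroup_counts: dict[str, int]
    pattern_probs: dict[str, dict[str, float]]
    model: IntensityModel = IntensityModel()
    n_probes: int = 2000
    n_females: int = 20
    missing_rate: float = 0.05
    jitter_probes: int = 2

    def __post_init__(self) -> None:
        for hg, probs in self.pattern_probs.items():
            total = sum(probs.values())
            if total > 1 + 1e-9:
                raise ValueError(
                    f"pattern probabilities for {hg!r} sum to {total:.3f} > 1"
                )
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative pattern probability for {hg!r}")


@dataclass
class SimulatedCohort:
    """A simulated cohort with its ground truth."""

    manifest: ProbeManifest
    regions: list[RegionDef]
    annotation: ProbeAnnotation
    catalog: list[PatternSignature]
    sample_ids: list[str]
    truth: pd.DataFrame  # sample, sex, haplogroup (label), node, patterns
    events: dict[str, list[CNVEvent]]
    genotypes: pd.DataFrame  # samples x SNP ids (allele strings, "." missing)
    profiles: np.ndarray | None  # (n_samples, n_probes)
    female_ids: list[str] = field(default_factory=list)
    female_profiles: np.ndarray | None = None


def default_cohort_config(
    scale: float = 1.0, n_probes: int = 2000, **overrides
) -> CohortConfig:
    """Cohort configuration mirroring the reference cohort: per-haplogroup
    sample counts from the bundled any-CNV table and carrier probabilities
    from the per-pattern count tables."""
    table1 = defaults.load_table1_counts()
    table2 = defaults.load_table2_counts()
    counts = {
        hg: max(1, round(scale * int(row["n"]))) for hg, row in table2.iterrows()
    }
    probs: dict[str, dict[str, float]] = {}
    for hg, row in table2.iterrows():
        n = float(row["n"])
        per_pattern: dict[str, float] = {}
        if hg in table1.index:
            for pattern in table1.columns.drop("n"):
                c = int(table1.loc[hg, pattern])
                if c:
                    per_pattern[pattern] = c / n
        for pattern, c in defaults.EXTRA_PATTERN_COUNTS.get(hg, {}).items():
            per_pattern[pattern] = per_pattern.get(pattern, 0.0) + c / n
        probs[hg] = per_pattern
    return CohortConfig(
        haplogroup_counts=counts, pattern_probs=probs, n_probes=n_probes, **overrides
    )


def simulate_cohort(
    config: CohortConfig,
    seed: int,
    tree: YTree | None = None,
    regions: Sequence[RegionDef] | None = None,
    catalog: Sequence[PatternSignature] | None = None,
    intensities: bool = True,
) -> SimulatedCohort:
    """Draw a full cohort: truth CNV events, intensity profiles (unless
    ``intensities=False``) and genotypes, plus background females."""
    from .haplogroup import load_tree  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    if tree is None:
        tree = load_tree(defaults.default_tree_path())
    regions = list(regions) if regions is not None else defaults.default_region_map()
    catalog = (
        list(catalog)
        if catalog is not None
        else load_catalog(defaults.default_catalog_path())
    )
    by_name = {sig.name: sig for sig in catalog}
    for hg, probs in config.pattern_probs.items():
        unknown = set(probs) - set(by_name)
        if unknown:
            raise ValueError(f"{hg}: pattern(s) not in catalog: {sorted(unknown)}")

    manifest = synthetic_manifest(n_probes=config.n_probes, regions=regions)
    annotation = assign_probes(manifest, regions)

    sample_ids: list[str] = []
    rows = []
    events: dict[str, list[CNVEvent]] = {}
    genotype_rows = {}
    profiles = [] if intensities else None
    i = 0
    for hg, count in config.haplogroup_counts.items():
        node = _LABEL_TO_NODE.get(hg, hg)
        if node not in tree:
            raise ValueError(f"haplogroup {hg!r} (node {node!r}) not in tree")
        probs = config.pattern_probs.get(hg, {})
        names = list(probs)
        p = np.array([probs[n] for n in names] + [1.0 - sum(probs.values())])
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        for _ in range(count):
            sample = f"S{i:05d}"
            i += 1
            sample_ids.append(sample)
            choice = rng.choice(len(names) + 1, p=p)
            patterns: list[str] = [] if choice == len(names) else [names[choice]]
            evs: list[CNVEvent] = []
            for pattern in patterns:
                evs.extend(
                    events_for_signature(
                        by_name[pattern],
                        annotation,
                        manifest,
                        jitter_probes=config.jitter_probes,
                        rng=rng,
                    )
                )
            events[sample] = evs
            rows.append(
                {
                    "sample": sample,
                    "sex": "male",
                    "haplogroup": hg,
                    "node": node,
                    "patterns": ";".join(patterns),
                }
            )
            genotype_rows[sample] = simulate_genotypes(
                tree, node, missing_rate=config.missing_rate, rng=rng
            )
            if profiles is not None:
                profiles.append(
                    simulate_sample(manifest, config.model, "male", evs, seed=rng)
                )

    female_ids = [f"F{j:04d}" for j in range(config.n_females)]
    female_profiles = None
    if intensities and config.n_females:
        female_profiles = np.vstack(
            [
                simulate_sample(manifest, config.model, "female", (), seed=rng)
                for _ in female_ids
            ]
        )

    return SimulatedCohort(
        manifest=manifest,
        regions=regions,
        annotation=annotation,
        catalog=list(catalog),
        sample_ids=sample_ids,
        truth=pd.DataFrame(rows).set_index("sample"),
        events=events,
        genotypes=pd.DataFrame.from_dict(genotype_rows, orient="index").fillna(MISSING),
        profiles=np.vstack(profiles) if profiles else None,
        female_ids=female_ids,
        female_profiles=female_profiles,
    )
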