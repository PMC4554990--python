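"""End-to-end orchestration: simulate -> qc -> segment -> classify ->
haplogroup -> enrich -> pca -> report.

``run_pipeline`` drives every stage off one seeded configuration and
writes TSV/JSON outputs plus a plain-text summary to the run directory;
outputs are deterministic given (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import defaults
from .background import flag_high_background, infer_sex
from .enrichment import (
    build_table,
    fisher_exact,
    frequency_report,
    g_test,
    pearson_chi_square,
)
from .haplogroup import assign_haplogroup, backmerge, load_tree
from .patterns import classify, load_catalog, region_copy_states
from .pca import encode, run_pca
from .probe_map import ProbeManifest, assign_probes, load_manifest
from .segmentation import (
    SegmentationParams,
    call_states,
    density_filter,
    segment,
    segments_to_frame,
)
from .synthetic import CohortConfig, default_cohort_config, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "plot_profile"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; unset paths fall back to bundled defaults."""

    outdir: str | Path = "ycnv_run"
    seed: int = 0
    cohort: CohortConfig | None = None  # None -> default cohort at `scale`
    scale: float = 0.2
    n_probes: int = 2000
    manifest_path: str | None = None
    catalog_path: str | None = None
    tree_path: str | None = None
    seg_params: SegmentationParams = dc_field(default_factory=SegmentationParams)
    coverage_threshold: float = 0.8
    qc_window: int = 3
    qc_threshold: float = defaults.MU_ONE_COPY
    mc_replicates: int = 10_000
    pca_components: int = 2

    def validate_paths(self) -> None:
        for name in ("manifest_path", "catalog_path", "tree_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} does not exist: {value}")


def _stage(name: str, log: list[str], message: str) -> None:
    line = f"[{name}] {message}"
    logger.info(line)
    log.append(line)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline and return the output directory."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    catalog_path = config.catalog_path or defaults.default_catalog_path()
    tree_path = config.tree_path or defaults.default_tree_path()
    regions = defaults.default_region_map()
    catalog = load_catalog(catalog_path, regions=regions)
    tree = load_tree(tree_path)

    cohort_cfg = config.cohort or default_cohort_config(
        scale=config.scale, n_probes=config.n_probes
    )
    cohort = simulate_cohort(
        cohort_cfg, seed=config.seed, tree=tree, regions=regions, catalog=catalog
    )
    manifest = cohort.manifest
    if config.manifest_path:
        manifest = load_manifest(config.manifest_path)
    _stage(
        "simulate",
        log,
        f"{len(cohort.sample_ids)} males + {len(cohort.female_ids)} females, "
        f"{len(manifest)} probes",
    )

    # --- QC: sex inference and female high-background blacklist -----------
    sexes = {
        s: infer_sex(cohort.profiles[i]) for i, s in enumerate(cohort.sample_ids)
    }
    n_misclassified = sum(1 for v in sexes.values() if v != "male")
    blacklist = flag_high_background(
        cohort.female_profiles,
        cohort.profiles,
        manifest,
        window=config.qc_window,
        threshold=config.qc_threshold,
    )
    blacklist.write(outdir / "blacklist.tsv")
    keep = blacklist.mask(manifest)
    filtered = ProbeManifest(
        probe_ids=manifest.probe_ids[keep],
        positions=manifest.positions[keep],
        probe_classes=manifest.probe_classes[keep],
    )
    annotation = assign_probes(filtered, regions)
    _stage(
        "qc",
        log,
        f"{len(blacklist)} probes blacklisted; "
        f"{n_misclassified} sex misclassifications",
    )

    # --- segmentation and pattern classification --------------------------
    seg_frames = []
    pattern_calls: dict[str, list[str]] = {}
    call_rows = []
    for i, sample in enumerate(cohort.sample_ids):
        profile = cohort.profiles[i][keep]
        states = call_states(profile, config.seg_params)
        segs = density_filter(
            segment(states, filtered, profile, config.seg_params),
            config.seg_params.min_density,
        )
        seg_frames.append(segments_to_frame(segs, sample))
        vector = region_copy_states(
            segs, annotation, regions, config.coverage_threshold
        )
        calls = classify(vector, catalog, regions)
        pattern_calls[sample] = [c.pattern for c in calls]
        for c in calls:
            call_rows.append(
                {
                    "sample": sample,
                    "pattern": c.pattern,
                    "regions": ",".join(c.regions),
                    "novel": c.novel,
                    "signature": c.signature_string,
                }
            )
    non_empty = [f for f in seg_frames if len(f)]
    seg_df = (
        pd.concat(non_empty, ignore_index=True)
        if non_empty
        else segments_to_frame([], "")
    )
    seg_df.to_csv(outdir / "segments.tsv", sep="\t", index=False)
    calls_df = pd.DataFrame(
        call_rows, columns=["sample", "pattern", "regions", "novel", "signature"]
    )
    calls_df.to_csv(outdir / "pattern_calls.tsv", sep="\t", index=False)
    n_carriers = sum(1 for v in pattern_calls.values() if v)
    _stage(
        "classify",
        log,
        f"{n_carriers} carriers, {len(call_rows)} pattern calls "
        f"({int(calls_df['novel'].sum()) if len(calls_df) else 0} novel)",
    )

    # --- haplogroup assignment --------------------------------------------
    major_set = set(defaults.MAJOR_HAPLOGROUPS)
    hg_rows = []
    assigned: dict[str, str] = {}
    funnel = {"assigned": 0, "excluded_internal": 0, "ambiguous": 0, "unassigned": 0}
    for sample in cohort.sample_ids:
        genotype = cohort.genotypes.loc[sample].to_dict()
        call = backmerge(assign_haplogroup(genotype, tree), tree, major_set)
        if call.status in ("assigned", "internal_with_exclusion"):
            label = defaults.MAJOR_LABELS.get(call.node, call.node)
            assigned[sample] = label
            funnel["assigned"] += 1
        else:
            funnel[call.status] += 1
        hg_rows.append(
            {
                "sample": sample,
                "status": call.status,
                "haplogroup": call.label if call.node else "",
                "excluded_children": ",".join(call.excluded_children),
                "n_supporting": call.n_supporting,
            }
        )
    pd.DataFrame(hg_rows).to_csv(outdir / "haplogroup_calls.tsv", sep="\t", index=False)
    _stage(
        "haplogroup",
        log,
        f"{funnel['assigned']} assigned to majors, "
        f"{funnel['excluded_internal']} internal-excluded, "
        f"{funnel['ambiguous']} ambiguous, {funnel['unassigned']} unassigned "
        f"(total {len(cohort.sample_ids)})",
    )

    # --- enrichment --------------------------------------------------------
    variants = sorted({p for v in pattern_calls.values() for p in v if p != "novel"})
    enrich_rows = []
    for variant in variants:
        table = build_table(
            assigned,
            pattern_calls,
            variant,
            row_order=[h for h in defaults.MAJOR_ORDER if h in set(assigned.values())],
        )
        try:
            chi = pearson_chi_square(table)
            g = g_test(table)
            fisher = fisher_exact(
                table, mc_replicates=config.mc_replicates, seed=config.seed
            )
            enrich_rows.append(
                {
                    "variant": variant,
                    "carriers": int(table.values[:, 0].sum()),
                    "chi2": chi.statistic,
                    "df": chi.df,
                    "chi2_p": chi.p,
                    "g": g.statistic,
                    "g_p": g.p,
                    "fisher_p": fisher.p,
                    "fisher_method": fisher.method,
                }
            )
        except ValueError as exc:
            logger.info("enrichment skipped for %s: %s", variant, exc)
    pd.DataFrame(enrich_rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    report = frequency_report(
        assigned,
        pattern_calls,
        row_order=[h for h in defaults.MAJOR_ORDER if h in set(assigned.values())],
    )
    report.table.to_csv(outdir / "cnv_frequencies.tsv", sep="\t")
    _stage(
        "enrich",
        log,
        f"{len(variants)} variants tested; overall carrier fraction "
        f"{report.overall_pct}% of {report.total_n}",
    )

    # --- PCA ---------------------------------------------------------------
    pca = run_pca(encode(cohort.genotypes), n_components=config.pca_components)
    scores = pd.DataFrame(
        pca.scores,
        index=cohort.genotypes.index,
        columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
    )
    scores["haplogroup"] = cohort.truth["haplogroup"]
    scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    _stage(
        "pca",
        log,
        "explained: "
        + ", ".join(f"PC{i+1} {100*v:.1f}%" for i, v in enumerate(pca.explained)),
    )

    summary = {
        "seed": config.seed,
        "n_samples": len(cohort.sample_ids),
        "n_probes": len(manifest),
        "n_blacklisted": len(blacklist),
        "funnel": funnel,
        "n_carriers": n_carriers,
        "overall_carrier_pct": report.overall_pct,
        "variants_tested": variants,
        "pca_explained": [float(v) for v in pca.explained],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "pipeline.log").write_text("\n".join(log) + "\n")
    return outdir


def plot_profile(
    profile: np.ndarray,
    manifest: ProbeManifest,
    regions: Sequence = (),
    segments: Sequence = (),
    path: str | Path = "profile.png",
) -> Path:
    """Per-probe log2-ratio scatter with region colouring and segment
    extents marked by horizontal staples (gains above, losses below)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 4))
    mb = manifest.positions / 1e6
    ax.scatter(mb, profile, s=2, c="0.6", label="probes")
    cmap = plt.get_cmap("tab20")
    for i, region in enumerate(regions):
        ax.axvspan(
            region.start / 1e6,
            region.stop / 1e6,
            alpha=0.15,
            color=cmap(i % 20),
        )
        ax.text(
            (region.start + region.stop) / 2e6,
            ax.get_ylim()[1],
            region.name,
            fontsize=5,
            rotation=90,
            ha="center",
            va="top",
        )
    for seg in segments:
        y = 1.1 if seg.state == "gain" else -2.6
        ax.plot([seg.start / 1e6, seg.stop / 1e6], [y, y], lw=2, color="red")
    ax.set_xlabel("chrY position (Mb)")
    ax.set_ylabel("log2 ratio")
    ax.set_ylim(-3.2, 1.5)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
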