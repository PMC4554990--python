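"""Bundled defaults: region map, pattern catalog, haplogroup tree and the
reference-cohort count tables used by the demo and acceptance analyses.

The intensity anchors are the three empirical log2-ratio state means of the
Affymetrix-6.0-style MSY probe set: about -0.47 for single-copy male
sequence, -2.02 for absent sequence (female background) and 0.04 for
duplicated sequence.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .probe_map import (
    RegionDef,
    build_regions,
    load_region_pairing,
    load_sts_table,
)

__all__ = [
    "MU_ONE_COPY",
    "MU_ZERO_COPY",
    "MU_TWO_COPY",
    "DEFAULT_SIGMA",
    "MSY_SPAN",
    "REAL_ARRAY_N_PROBES",
    "REAL_ARRAY_N_SNP",
    "DESERT_REGIONS",
    "HOT_REGIONS",
    "HOT_MEAN",
    "MAJOR_HAPLOGROUPS",
    "MAJOR_LABELS",
    "MAJOR_ORDER",
    "data_path",
    "default_sts_table",
    "default_region_map",
    "default_catalog_path",
    "default_tree_path",
    "load_table1_counts",
    "load_table2_counts",
    "EXTRA_PATTERN_COUNTS",
]

# Empirical log2-ratio state means and the default per-probe noise s.d.
MU_ONE_COPY = -0.47
MU_ZERO_COPY = -2.02
MU_TWO_COPY = 0.04
DEFAULT_SIGMA = 0.25

# Male-specific region span covered by the synthetic manifest (1-based bp).
MSY_SPAN = (2_650_000, 28_800_000)

# The real array carries 8179 MSY probes: 288 SNP + 7891 CN.
REAL_ARRAY_N_PROBES = 8179
REAL_ARRAY_N_SNP = 288

# AZFc amplicons with no probe coverage on the array; the synthetic
# manifest leaves them probe-free so their copy state is never observed
# directly (state "no-probe" downstream).
DESERT_REGIONS = frozenset({"g1", "r1", "r2", "g4"})

# Probe coverage of the real array is not uniform: the 35-kb window at the
# 3' end of USP9Y carries 21 probes, about twice the array-wide density.
# Regions listed here are filled to the given probe count (at real scale,
# proportionally fewer for smaller synthetic manifests).
DENSE_REGIONS = {"USP9Y-3p": 21}

# Three intervals where female background intensity is elevated (mirroring
# the high-background windows excluded from CNV calling), with their mean.
HOT_REGIONS = (
    (3_100_000, 3_180_000),
    (8_500_000, 8_580_000),
    (16_800_000, 16_880_000),
)
HOT_MEAN = -0.30

# The 12 major clades used for backmerging (tree node names) and the labels
# under which the three exclusion-defined majors are tabulated.
MAJOR_HAPLOGROUPS = (
    "C-M130",
    "D-M174",
    "E-M96",
    "F-M89",
    "G-M201",
    "I-M170",
    "J-M304",
    "KLT-M9",
    "NO-M214",
    "O-M175",
    "Q-M242",
    "R-M207",
)
MAJOR_LABELS = {
    "F-M89": "F-M89(xM1329)",
    "KLT-M9": "KLT-M9(xM526)",
    "NO-M214": "NO-M214(xM175)",
}
MAJOR_ORDER = tuple(MAJOR_LABELS.get(n, n) for n in MAJOR_HAPLOGROUPS)


def data_path(filename: str):
    """Path-like handle to a bundled data file."""
    return resources.files("ycnv.data").joinpath(filename)


def default_sts_table() -> pd.DataFrame:
    return load_sts_table(data_path("sts_markers.tsv"))


def default_region_map() -> list[RegionDef]:
    """The bundled STS-delimited MSY region map (hg19-style coordinates)."""
    return build_regions(
        default_sts_table(), load_region_pairing(data_path("region_pairing.tsv"))
    )


def default_catalog_path():
    return data_path("pattern_catalog.yaml")


def default_tree_path():
    return data_path("y_tree.txt")


def load_table1_counts() -> pd.DataFrame:
    """Carrier counts per haplogroup for the ten overrepresented patterns."""
    df = pd.read_csv(data_path("table1_counts.tsv"), sep="\t", comment="#")
    return df.set_index("haplogroup")


def load_table2_counts() -> pd.DataFrame:
    """Cohort sizes and any-CNV carrier counts per major haplogroup."""
    df = pd.read_csv(data_path("table2_counts.tsv"), sep="\t", comment="#")
    return df.set_index("haplogroup")


# Carrier counts for the 15 patterns without significant haplogroup
# association, allocated so that each haplogroup's total carrier count
# matches the reference cohort (table2_counts.tsv).  Together with
# table1_counts.tsv this fully specifies the default cohort simulation.
EXTRA_PATTERN_COUNTS: dict[str, dict[str, int]] = {
    "C-M130": {"gr/gr dupl (c9)": 1},
    "E-M96": {"prior P5 post P4 dupl": 6, "P3 del": 4, "gr/gr dupl (c9)": 10},
    "G-M201": {"gr/gr dupl (c9)": 3},
    "I-M170": {"gr/gr dupl (c9)": 4, "IR2 dupl": 2},
    "J-M304": {"gr/gr dupl (c9)": 8, "b2/b4 dupl (c21)": 4},
    "KLT-M9(xM526)": {"gr/gr dupl (c9)": 1},
    "NO-M214(xM175)": {"P6 dupl": 1},
    "O-M175": {"gr/gr dupl (c9)": 6, "b2/b4 del dupl (c9)": 3},
    "Q-M242": {"gr/gr dupl (c9)": 2},
    "R-M207": {
        "gr/gr dupl (c9)": 3,
        "P6 dupl": 4,
        "IR2 dupl": 3,
        "IR2 del": 1,
        "Y1Y2 dupl": 1,
        "distal gr dupl": 1,
        "p-arm dupl (PCDH11Y)": 1,
        "p-arm dupl (AMELY)": 1,
        "q-prox dupl (NLGN4Y)": 1,
        "q-arm del": 1,
        "q-arm del + U3 del": 1,
        "b2/b4 dupl (c21)": 6,
        "b2/b4 del dupl (c9)": 5,
    },
}
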