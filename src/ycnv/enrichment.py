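"""Haplogroup x CNV-carrier contingency tables and enrichment statistics.

Provides Pearson chi-square, the likelihood-ratio G statistic, Fisher's
exact test (exact for 2x2, fixed-margin Monte Carlo for larger tables),
per-cell standardized (Pearson) and adjusted residuals, and the carrier
frequency report.  Ambiguous and unassigned individuals never enter the
tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "FisherResult",
    "Residuals",
    "FrequencyReport",
    "build_table",
    "pearson_chi_square",
    "g_test",
    "fisher_exact",
    "residuals",
    "frequency_report",
    "frequency_report_from_counts",
]


class DegenerateTableError(ValueError):
    """Raised for tables with an all-zero row or column."""


@dataclass(frozen=True)
class ContingencyTable:
    """Non-negative integer counts with labeled rows and columns."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("negative counts in contingency table")
        if not np.issubdtype(values.dtype, np.integer):
            raise ValueError("contingency table counts must be integers")

    @classmethod
    def from_array(
        cls,
        values,
        rows: Sequence[str] | None = None,
        cols: Sequence[str] | None = None,
    ) -> "ContingencyTable":
        arr = np.asarray(values, dtype=np.int64)
        rows = rows if rows is not None else [f"r{i}" for i in range(arr.shape[0])]
        cols = cols if cols is not None else [f"c{j}" for j in range(arr.shape[1])]
        return cls(pd.DataFrame(arr, index=list(rows), columns=list(cols)))

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def row_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.values.sum())

    @property
    def expected(self) -> np.ndarray:
        return np.outer(self.row_totals, self.col_totals) / self.grand_total

    def check_nondegenerate(self) -> None:
        if (self.row_totals == 0).any() or (self.col_totals == 0).any():
            raise DegenerateTableError("table has an all-zero row or column")


def build_table(
    haplogroup_calls: Mapping[str, str],
    pattern_calls: Mapping[str, Iterable[str]],
    variant: str,
    catalog_names: Iterable[str] | None = None,
    row_order: Sequence[str] | None = None,
) -> ContingencyTable:
    """Carrier/non-carrier table of ``variant`` across assigned haplogroups.

    ``haplogroup_calls`` maps sample -> major haplogroup label (samples with
    ambiguous/unassigned/excluded status must already be absent); a sample
    with at least one matching pattern call is a carrier, counted once.
    """
    if catalog_names is not None and variant not in set(catalog_names):
        raise ValueError(f"variant {variant!r} not in catalog")
    rows: dict[str, list[int]] = {}
    order = list(row_order) if row_order is not None else sorted(
        set(haplogroup_calls.values())
    )
    for hg in order:
        rows[hg] = [0, 0]
    for sample, hg in haplogroup_calls.items():
        if hg not in rows:
            continue
        carried = variant in set(pattern_calls.get(sample, ()))
        rows[hg][0 if carried else 1] += 1
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["carrier", "non_carrier"]
    ).astype(np.int64)
    return ContingencyTable(df)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square without continuity correction."""
    table.check_nondegenerate()
    stat, p, df, _ = stats.chi2_contingency(table.values, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p))


def g_test(table: ContingencyTable) -> ChiSquareResult:
    """Likelihood-ratio G = 2 sum O ln(O/E); zero cells contribute 0."""
    table.check_nondegenerate()
    stat, p, df, _ = stats.chi2_contingency(
        table.values, correction=False, lambda_="log-likelihood"
    )
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p))


@dataclass(frozen=True)
class FisherResult:
    p: float
    method: str  # "exact" | "monte-carlo"
    replicates: int | None = None
    se: float | None = None
    seed: int | None = None


def _log_table_prob(values: np.ndarray) -> float:
    """Log probability of a table under the fixed-margins null."""
    r = values.sum(axis=1)
    c = values.sum(axis=0)
    n = values.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(values + 1).sum()
    )


def fisher_exact(
    table: ContingencyTable,
    mc_replicates: int = 1_000_000,
    seed: int | None = 0,
) -> FisherResult:
    """Two-sided Fisher's exact test.

    2x2 tables are evaluated exactly (sum of hypergeometric probabilities
    not exceeding the observed table's).  Larger tables use fixed-margin
    Monte Carlo: ``mc_replicates`` tables are drawn with the observed
    margins and the p-value is the fraction whose null probability is at
    most the observed one (with the standard +1 correction); the Monte
    Carlo standard error is reported.
    """
    table.check_nondegenerate()
    values = table.values
    if values.shape == (2, 2):
        _, p = stats.fisher_exact(values, alternative="two-sided")
        return FisherResult(p=float(p), method="exact")
    if mc_replicates < 1:
        raise ValueError("mc_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(table.row_totals, table.col_totals)
    observed = _log_table_prob(values)
    hits = 0
    remaining = mc_replicates
    batch = 100_000
    while remaining > 0:
        m = min(batch, remaining)
        draws = sampler.rvs(m, random_state=rng)
        logp = (
            gammaln(table.row_totals + 1).sum()
            + gammaln(table.col_totals + 1).sum()
            - gammaln(table.grand_total + 1)
            - gammaln(draws + 1).sum(axis=(-2, -1))
        )
        hits += int(np.sum(logp <= observed + 1e-9))
        remaining -= m
    p = (hits + 1) / (mc_replicates + 1)
    se = float(np.sqrt(p * (1 - p) / mc_replicates))
    return FisherResult(
        p=float(p), method="monte-carlo", replicates=mc_replicates, se=se, seed=seed
    )


@dataclass(frozen=True)
class Residuals:
    """Standardized (Pearson) and adjusted per-cell residuals."""

    pearson: pd.DataFrame
    adjusted: pd.DataFrame


def residuals(table: ContingencyTable) -> Residuals:
    """Pearson residuals (O-E)/sqrt(E) and adjusted residuals
    (O-E)/sqrt(E(1-row/N)(1-col/N))."""
    table.check_nondegenerate()
    observed = table.values.astype(float)
    expected = table.expected
    pearson = (observed - expected) / np.sqrt(expected)
    n = table.grand_total
    row_frac = table.row_totals / n
    col_frac = table.col_totals / n
    denom = np.sqrt(expected * np.outer(1 - row_frac, 1 - col_frac))
    adjusted = (observed - expected) / denom
    idx, cols = table.counts.index, table.counts.columns
    return Residuals(
        pearson=pd.DataFrame(pearson, index=idx, columns=cols),
        adjusted=pd.DataFrame(adjusted, index=idx, columns=cols),
    )


@dataclass(frozen=True)
class FrequencyReport:
    """Per-haplogroup carrier counts and percentages (1 d.p. convention)."""

    table: pd.DataFrame  # index haplogroup; n, pct_total, carriers, pct_carriers
    total_n: int
    total_carriers: int

    @property
    def overall_pct(self) -> float:
        if self.total_n == 0:
            return float("nan")
        return round(100.0 * self.total_carriers / self.total_n, 1)


def frequency_report_from_counts(
    counts: pd.DataFrame, exclude: Iterable[str] = ()
) -> FrequencyReport:
    """Frequency report from a per-haplogroup counts frame (columns ``n``
    and ``carriers``); excluded haplogroups leave both numerator and
    denominator."""
    exclude = set(exclude)
    unknown = exclude - set(counts.index)
    if unknown:
        raise ValueError(f"exclude lists unknown haplogroup(s): {sorted(unknown)}")
    kept = counts.loc[[h for h in counts.index if h not in exclude]].copy()
    total_n = int(kept["n"].sum())
    total_carriers = int(kept["carriers"].sum())
    if total_n:
        kept["pct_total"] = (100.0 * kept["n"] / total_n).round(1)
    else:
        kept["pct_total"] = np.nan
    kept["pct_carriers"] = (100.0 * kept["carriers"] / kept["n"]).round(1)
    kept = kept[["n", "pct_total", "carriers", "pct_carriers"]]
    return FrequencyReport(table=kept, total_n=total_n, total_carriers=total_carriers)


def frequency_report(
    haplogroup_calls: Mapping[str, str],
    pattern_calls: Mapping[str, Iterable[str]],
    exclude: Iterable[str] = (),
    row_order: Sequence[str] | None = None,
) -> FrequencyReport:
    """Any-CNV carrier report per haplogroup.

    A sample counts as a carrier once regardless of how many patterns it
    carries.  ``exclude`` drops whole haplogroups from numerator and
    denominator alike.
    """
    order = list(row_order) if row_order is not None else sorted(
        set(haplogroup_calls.values())
    )
    counts = pd.DataFrame(0, index=order, columns=["n", "carriers"], dtype=np.int64)
    for sample, hg in haplogroup_calls.items():
        if hg not in counts.index:
            continue
        counts.loc[hg, "n"] += 1
        if len(set(pattern_calls.get(sample, ()))):
            counts.loc[hg, "carriers"] += 1
    return frequency_report_from_counts(counts, exclude=exclude)
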