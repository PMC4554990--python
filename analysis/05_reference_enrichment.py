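#!/usr/bin/env python
"""Enrichment statistics on the bundled reference-cohort count tables.

Rebuilds each overrepresented pattern's 12x2 haplogroup-by-carrier table
from the bundled counts (1506 haplogroup-assigned males), computes Pearson
chi-square, likelihood-ratio G, Fisher (Monte Carlo for 12x2) and both
residual conventions, plus the any-CNV frequency report with and without
the NO-M214(xM175) haplogroup.  Writes results/reference_enrichment.tsv
and results/reference_frequencies.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ycnv import defaults
from ycnv.enrichment import (
    ContingencyTable,
    fisher_exact,
    frequency_report_from_counts,
    g_test,
    pearson_chi_square,
    residuals,
)

OUT = Path("results")
MC_REPLICATES = 100_000
SEED = 11


def main() -> None:
    OUT.mkdir(exist_ok=True)
    t1 = defaults.load_table1_counts()
    t2 = defaults.load_table2_counts()
    n = int(t1["n"].sum())

    rows = []
    for variant in t1.columns.drop("n"):
        carriers = t1[variant]
        table = ContingencyTable.from_array(
            np.column_stack([carriers, t1["n"] - carriers]).astype(np.int64),
            rows=list(t1.index), cols=["carrier", "non_carrier"],
        )
        chi = pearson_chi_square(table)
        g = g_test(table)
        fisher = fisher_exact(table, mc_replicates=MC_REPLICATES, seed=SEED)
        res = residuals(table)
        top = res.adjusted["carrier"].idxmax()
        rows.append({
            "variant": variant,
            "carriers": int(carriers.sum()),
            "pct_of_cohort": round(100 * carriers.sum() / n, 2),
            "chi2": round(chi.statistic, 1),
            "chi2_p": chi.p,
            "g": round(g.statistic, 1),
            "g_p": g.p,
            "fisher_mc_p": fisher.p,
            "top_haplogroup": top,
            "top_pearson_residual": round(float(res.pearson.loc[top, "carrier"]), 1),
            "top_adjusted_residual": round(float(res.adjusted.loc[top, "carrier"]), 1),
        })
    enrich = pd.DataFrame(rows)
    enrich.to_csv(OUT / "reference_enrichment.tsv", sep="\t", index=False)
    print(enrich[["variant", "carriers", "pct_of_cohort", "chi2_p",
                  "top_haplogroup", "top_pearson_residual"]].to_string(index=False))

    rep = frequency_report_from_counts(t2)
    rep.table.to_csv(OUT / "reference_frequencies.tsv", sep="\t")
    rep_x = frequency_report_from_counts(t2, exclude=["NO-M214(xM175)"])
    print(f"\nany-CNV carriers: {rep.total_carriers}/{rep.total_n} "
          f"({rep.overall_pct}%); excluding NO-M214(xM175): {rep_x.overall_pct}%")

    case_control = ContingencyTable.from_array([[13, 126], [21, 111]])
    print(f"case/control Fisher p = {fisher_exact(case_control).p:.3f} "
          "(13/139 cases vs 21/132 controls)")


if __name__ == "__main__":
    main()
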