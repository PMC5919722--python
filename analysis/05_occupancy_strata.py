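#!/usr/bin/env python
"""Chromatin occupancy and line-to-line expression variability.

Computes each gene's CV across the 99 lines where it is two-dose (per-line
replicate means; genes on the deletion-bearing arm 2L excluded) and
compares occupancy-flagged vs unflagged genes within strata: X vs
autosomes, housekeeping (tau below the 5th percentile) vs not, EBox motif
presence, and NSL activation — per sex.
"""
import sys
import warnings
from pathlib import Path

import pandas as pd

from dosevar import workflows as wf
from dosevar.occupancy import flag_occupancy, gene_cv_table, housekeeping_flag, \
    stratified_compare
from dosevar.synth import CohortConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    warnings.simplefilter("ignore", UserWarning)
    ca = wf.prepare(CohortConfig(), SEED)
    genes = ca.matrix.genes.set_index("gene_id")
    flags = flag_occupancy(ca.matrix.genes, ca.cohort.peaks)
    auto = genes["arm"] != "X"
    strata_sets = {
        "overall": None,
        "X_vs_auto": genes["arm"].map(
            lambda a: pd.NA if pd.isna(a) else ("X" if a == "X" else "auto")),
        "housekeeping": housekeeping_flag(genes["tau"]).map(
            {True: "housekeeping", False: "non-housekeeping"}).where(auto),
        "ebox": genes["ebox"].map({True: "EBox+", False: "EBox-"}).where(auto),
        "nsl": genes["nsl_activated"].map(
            {True: "NSL-activated", False: "NSL-silent"}).where(auto),
    }

    rows = []
    for cond in ca.conditions():
        cv_table = gene_cv_table(ca.matrix, ca.dose_table, cond, ca.cutoff)
        for panel, strata in strata_sets.items():
            for cmp in stratified_compare(cv_table, flags, strata=strata,
                                          flag_name="MOF"):
                rows.append({"sex": cond.sex, "panel": panel, **cmp.__dict__})
                print(f"[{cond.sex}/{panel}] {cmp.label_a} (n={cmp.n_a}, "
                      f"median CV {cmp.median_a:.4f}) vs {cmp.label_b} "
                      f"(n={cmp.n_b}, median CV {cmp.median_b:.4f}): "
                      f"p = {cmp.p_value:.3g}")
    pd.DataFrame(rows).to_csv(RESULTS / "occupancy_strata.tsv", sep="\t",
                              index=False, float_format="%.6g")
    print(f"wrote {RESULTS / 'occupancy_strata.tsv'}")


if __name__ == "__main__":
    sys.exit(main())
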