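#!/usr/bin/env python
"""Generate the default synthetic deficiency-line cohort and summarise it.

The cohort: 99 deletion lines on chromosome arm 2L, each removing 40
contiguous genes; two replicates per line for each sex; ~11,800 genes across
six arms plus 92 spike-ins; a log-normal intergenic background from which
the expressed-gene cutoff is derived. Writes a structural summary and the
head of the planted truth table under results/; the full cohort tables can
be exported with `dosevar generate` (they run to ~50 MB and are therefore
not kept here).
"""
import sys
from pathlib import Path

import pandas as pd

from dosevar import workflows as wf
from dosevar.synth import CohortConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = CohortConfig()
    ca = wf.prepare(config, SEED)
    matrix = ca.matrix
    truth = ca.cohort.truth

    n_one_dose = int((ca.dose_table.codes == 1).sum())
    summary = pd.DataFrame([
        ("seed", SEED),
        ("genes", config.n_genes),
        ("spike_ins", config.spike_in_count),
        ("df_lines", config.n_df_lines),
        ("genes_per_df", config.genes_per_df),
        ("samples", matrix.shape[1]),
        ("one_dose_measurement_slots", n_one_dose * len(config.sexes)),
        ("unique_one_dose_genes", int((ca.dose_table.codes == 1).any(axis=1).sum())),
        ("fpkm_cutoff", round(ca.cutoff.value, 6)),
        ("occupancy_flagged_genes", int(truth.genes["occupancy"].sum())),
        ("housekeeping_genes", int(truth.genes["housekeeping"].sum())),
    ], columns=["quantity", "value"])
    summary.to_csv(RESULTS / "cohort_summary.tsv", sep="\t", index=False)
    truth.genes.head(25).to_csv(RESULTS / "truth_genes_head.tsv", sep="\t",
                                index=False, float_format="%.5g")

    print(f"cohort: {matrix.shape[0]} rows x {matrix.shape[1]} samples "
          f"(seed {SEED})")
    print(f"expressed-gene FPKM cutoff from intergenic background: "
          f"{ca.cutoff.value:.4f}")
    print(f"{n_one_dose} one-dose (gene, line) slots per sex; "
          f"{int((ca.dose_table.codes == 1).any(axis=1).sum())} distinct genes "
          "are one-dose in at least one line")
    print(f"wrote {RESULTS / 'cohort_summary.tsv'}")


if __name__ == "__main__":
    sys.exit(main())
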