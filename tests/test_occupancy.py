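"""Occupancy flagging, housekeeping calls, and stratified CV comparisons."""
import numpy as np
import pandas as pd
import pytest

from dosevar.expression_io import PeakSet
from dosevar.occupancy import (
    flag_occupancy,
    gene_cv_table,
    housekeeping_flag,
    stratified_compare,
)
from dosevar.variability import Condition


def _genes(rows):
    frame = pd.DataFrame(rows, columns=["gene_id", "arm", "start", "end"])
    frame["is_spike_in"] = False
    return frame


class TestFlagOccupancy:
    def test_overlap_and_half_open_adjacency(self):
        genes = _genes([("a", "2L", 100, 200), ("b", "2L", 100, 200)])
        peaks = PeakSet("MOF", (("2L", 150, 300),))
        flags = flag_occupancy(genes, peaks)
        assert flags["a"] and flags["b"]
        adjacent = PeakSet("MOF", (("2L", 200, 300),))
        assert not flag_occupancy(genes, adjacent).any()

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 10_000, 25)
        genes = _genes([(f"g{i}", "3R", int(s), int(s) + 500) for i, s in enumerate(starts)])
        peak_starts = rng.integers(0, 10_000, 8)
        peaks = PeakSet("MOF", tuple(("3R", int(s), int(s) + 300) for s in peak_starts))
        flags = flag_occupancy(genes, peaks)
        for row in genes.itertuples():
            expected = any(row.start < pe and row.end > ps
                           for _, ps, pe in peaks.intervals)
            assert flags[row.gene_id] == expected

    def test_arm_mismatch_never_flags(self):
        genes = _genes([("a", "2L", 100, 200)])
        peaks = PeakSet("MOF", (("2R", 100, 200),))
        assert not flag_occupancy(genes, peaks).any()


class TestHousekeepingFlag:
    def test_percentile_count(self):
        tau = pd.Series(np.arange(100) / 100.0,
                        index=[f"g{i}" for i in range(100)])
        flags = housekeeping_flag(tau)
        # threshold = 4.95th value; tau strictly below it: 0.00 .. 0.04
        assert int(flags.sum()) == 5

    def test_all_equal_none_flagged(self):
        tau = pd.Series([0.4] * 10, index=[f"g{i}" for i in range(10)])
        assert int(housekeeping_flag(tau).sum()) == 0

    def test_missing_tau_excluded_only(self):
        tau = pd.Series([0.01, 0.5, np.nan, 0.9], index=list("abcd"))
        flags = housekeeping_flag(tau, percentile=50)
        assert flags["a"] is not pd.NA and bool(flags["a"])
        assert pd.isna(flags["c"])

    def test_no_tau_rejected(self):
        with pytest.raises(ValueError):
            housekeeping_flag(pd.Series([np.nan, np.nan]))


class TestGeneCvTable:
    def test_planted_occupancy_effect(self, small_analysis):
        """Generator truth: flagged genes have shrunken noise, hence lower CV."""
        ca = small_analysis
        table = gene_cv_table(ca.matrix, ca.dose_table, Condition(sex="F"),
                              ca.cutoff)
        flags = ca.cohort.truth.genes.set_index("gene_id")["occupancy"]
        (cmp,) = stratified_compare(table, flags)
        assert cmp.median_a < cmp.median_b
        assert cmp.p_value < 0.01

    def test_excluded_arm_absent(self, small_analysis):
        ca = small_analysis
        table = gene_cv_table(ca.matrix, ca.dose_table, Condition(sex="M"),
                              ca.cutoff, exclude_arm="2L")
        arms = ca.matrix.genes.set_index("gene_id")["arm"]
        assert not (arms.loc[table["gene_id"]] == "2L").any()

    def test_min_lines_contract(self, toy_matrix):
        from dosevar.dose import assign_dose, fixed_cutoff
        from dosevar.expression_io import DfDefinition

        # only 3 lines exist; deleting g1 in one line leaves 2 usable -> drop
        dfs = [DfDefinition("L1", "2L", 0, 2500)]
        dose_table = assign_dose(toy_matrix.genes, dfs)
        with pytest.warns(UserWarning, match="fewer than 3"):
            table = gene_cv_table(toy_matrix, dose_table, Condition(sex="F"),
                                  fixed_cutoff(0.68), exclude_arm=None)
        assert "g1" not in set(table["gene_id"])
        # gx constant across lines -> CV exactly 0
        assert table.set_index("gene_id").loc["gx", "cv"] == 0.0

    def test_ordering_invariance(self, small_analysis):
        """CV table does not depend on sample (replicate/line) ordering."""
        ca = small_analysis
        table = gene_cv_table(ca.matrix, ca.dose_table, Condition(sex="F"), ca.cutoff)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ca.matrix.shape[1])
        from dosevar.expression_io import ExpressionMatrix

        shuffled = ExpressionMatrix(ca.matrix.genes,
                                    ca.matrix.samples.iloc[perm],
                                    ca.matrix.fpkm[:, perm])
        table2 = gene_cv_table(shuffled, ca.dose_table, Condition(sex="F"), ca.cutoff)
        merged = table.merge(table2, on="gene_id", suffixes=("", "_2"))
        assert len(merged) == len(table)
        np.testing.assert_allclose(merged["cv"], merged["cv_2"], rtol=1e-12)

    def test_all_samples_variant(self, small_analysis):
        ca = small_analysis
        a = gene_cv_table(ca.matrix, ca.dose_table, Condition(sex="F"),
                          ca.cutoff, per_line_mean=False)
        b = gene_cv_table(ca.matrix, ca.dose_table, Condition(sex="F"), ca.cutoff)
        merged = a.merge(b, on="gene_id", suffixes=("_all", "_mean"))
        # replicate noise adds dispersion: the all-samples CV dominates on average
        assert (merged["cv_all"] >= merged["cv_mean"]).mean() > 0.9


class TestStratifiedCompare:
    def test_degenerate_single_stratum_matches_unstratified(self, small_analysis):
        ca = small_analysis
        table = gene_cv_table(ca.matrix, ca.dose_table, Condition(sex="F"), ca.cutoff)
        flags = ca.cohort.truth.genes.set_index("gene_id")["occupancy"]
        (plain,) = stratified_compare(table, flags)
        strata = pd.Series("everything", index=flags.index)
        (strat,) = stratified_compare(table, flags, strata=strata)
        assert strat.p_value == plain.p_value
        assert strat.statistic == plain.statistic

    def test_planted_effect_in_every_stratum(self, small_analysis):
        ca = small_analysis
        table = gene_cv_table(ca.matrix, ca.dose_table, Condition(sex="F"), ca.cutoff)
        truth = ca.cohort.truth.genes.set_index("gene_id")
        strata = truth["arm"].map(lambda a: "X" if a == "X" else "auto")
        results = stratified_compare(table, truth["occupancy"], strata=strata)
        assert len(results) == 2
        for cmp in results:
            assert cmp.median_a < cmp.median_b

    def test_empty_side_reported_untested(self, small_analysis):
        ca = small_analysis
        table = gene_cv_table(ca.matrix, ca.dose_table, Condition(sex="F"), ca.cutoff)
        flags = pd.Series(True, index=pd.Index(table["gene_id"]))
        (cmp,) = stratified_compare(table, flags)
        assert cmp.n_b == 0 and np.isnan(cmp.p_value)

    def test_random_flags_calibrated(self, small_analysis):
        """Label permutation: random flags reject at ~ the nominal rate."""
        from scipy.stats import binom

        ca = small_analysis
        table = gene_cv_table(ca.matrix, ca.dose_table, Condition(sex="M"), ca.cutoff)
        rng = np.random.default_rng(123)
        gene_index = pd.Index(table["gene_id"])
        n_rej, n_perm = 0, 40
        for _ in range(n_perm):
            flags = pd.Series(rng.random(len(gene_index)) < 0.3, index=gene_index)
            (cmp,) = stratified_compare(table, flags)
            n_rej += cmp.p_value < 0.05
        assert n_rej <= binom.ppf(0.995, n_perm, 0.05)
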