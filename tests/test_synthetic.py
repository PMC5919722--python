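"""The synthetic cohort generator: determinism, structure, planted truth."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from dosevar.dose import derive_cutoff
from dosevar.synth import (
    CohortConfig,
    generate_cohort,
    generate_intergenic,
    head_config,
    intergenic_quantile,
)
from dosevar.variability import Condition, delta_matrix, delta_pools
from dosevar import workflows as wf


class TestGenerateCohort:
    def test_seed_determinism_bit_identical(self, small_config):
        a = generate_cohort(small_config, seed=3)
        b = generate_cohort(small_config, seed=3)
        np.testing.assert_array_equal(a.matrix.fpkm, b.matrix.fpkm)
        pd.testing.assert_frame_equal(a.truth.genes, b.truth.genes)
        assert a.dfs == b.dfs
        c = generate_cohort(small_config, seed=4)
        assert not np.array_equal(a.matrix.fpkm, c.matrix.fpkm)

    def test_structure_matches_config(self, small_config):
        cohort = generate_cohort(small_config, seed=0)
        cfg = small_config
        n_samples = cfg.n_df_lines * len(cfg.sexes) * cfg.replicates
        assert cohort.matrix.shape == (cfg.n_genes + cfg.spike_in_count, n_samples)
        assert len(cohort.dfs) == cfg.n_df_lines
        assert all(d.arm == cfg.df_arm for d in cohort.dfs)
        assert len(cohort.peaks.intervals) == cohort.truth.genes["occupancy"].sum()

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(arms={"2L": 10}, genes_per_df=40)

    def test_one_dose_expression_halved_on_average(self, small_analysis):
        """Planted dose term: one-dose log2 expression sits ~1 below the
        same gene's two-dose level, plus its gene-specific response rho."""
        ca = small_analysis
        truth = ca.cohort.truth.genes.set_index("gene_id")
        codes = ca.dose_table.matrix(gene_ids=ca.matrix.gene_ids)
        lines = ca.dose_table.line_ids
        samples = ca.matrix.samples
        diffs = []
        for g, gene in enumerate(ca.matrix.gene_ids[:ca.cohort.truth.config.n_genes]):
            one_lines = lines[codes[g] == 1]
            if not len(one_lines):
                continue
            one_cols = samples["line_id"].isin(one_lines).to_numpy()
            two_cols = ~one_cols
            diff = (np.log2(ca.matrix.fpkm[g, one_cols]).mean()
                    - np.log2(ca.matrix.fpkm[g, two_cols]).mean())
            diffs.append(diff - truth.loc[gene, "rho"])
        # per-gene residual carries the inflated line noise (~0.7 log2 sd
        # from a single one-dose line), so the mean over ~10^2 genes has
        # SE ~ 0.07
        assert np.mean(diffs) == pytest.approx(-1.0, abs=0.2)

    def test_head_preset_triplicates(self):
        cfg = head_config(arms={"2L": 40, "X": 80}, n_df_lines=6, genes_per_df=10,
                          spike_in_count=5, n_intergenic=200)
        cohort = generate_cohort(cfg, seed=1)
        assert cfg.replicates == 3
        assert cohort.matrix.samples["tissue"].eq("head").all()
        assert all(d.arm == "X" for d in cohort.dfs)
        dm = delta_matrix(cohort.matrix, Condition(sex="F", tissue="head"),
                          wf.analysis_cutoff(cfg, 1))
        assert dm.n_replicates == 3
        assert np.isfinite(dm.values).any()

    def test_null_config_removes_dose_effect(self, small_config):
        ca = wf.prepare(small_config.null(), seed=5)
        pools, cmp = wf.dose_comparison(ca)
        assert abs(cmp.median_a - cmp.median_b) < 0.05
        # but the expression halving is still planted
        _, alt_cmp = wf.dose_comparison(wf.prepare(small_config, seed=5))
        assert alt_cmp.median_a > alt_cmp.median_b + 0.05


class TestIntergenic:
    def test_cutoff_close_to_analytic_quantile(self, small_config):
        cfg = dataclasses.replace(small_config, n_intergenic=100_000)
        values = generate_intergenic(cfg, seed=0)
        spec = derive_cutoff(values)
        truth = intergenic_quantile(cfg, 95.0)
        assert spec.value == pytest.approx(truth, rel=0.02)

    def test_degenerate_sd_gives_constant(self, small_config):
        cfg = dataclasses.replace(small_config, intergenic_log2_sd=0.0)
        values = generate_intergenic(cfg, seed=0)
        spec = derive_cutoff(values)
        assert spec.value == pytest.approx(2.0 ** cfg.intergenic_log2_mean)

    def test_seeded_determinism(self, small_config):
        a = generate_intergenic(small_config, seed=9)
        b = generate_intergenic(small_config, seed=9)
        np.testing.assert_array_equal(a, b)


class TestPlantedOrderings:
    """Every planted effect is recoverable on the small cohort."""

    def test_spike_ins_quietest(self, small_analysis):
        ca = small_analysis
        dm = delta_matrix(ca.matrix, Condition(sex="M"), ca.cutoff)
        pools = delta_pools(dm, ca.dose_table, spike_in=ca.spike_mask)
        assert np.median(pools["spike_in"]) < np.median(pools["two_dose"])
        assert np.median(pools["spike_in"]) < np.median(pools["one_dose"])

    def test_female_noisier_than_male(self, small_analysis):
        cmp = wf.sex_comparison(small_analysis)
        assert cmp.median_a > cmp.median_b
        assert cmp.p_value < 0.01

    def test_male_x_not_inflated(self, small_analysis):
        """Under male-X compensation the single male X behaves at least as
        quietly as autosomal two-dose genes."""
        ca = small_analysis
        dm = delta_matrix(ca.matrix, Condition(sex="M"), ca.cutoff)
        arms = ca.matrix.genes["arm"].astype("string").fillna("").to_numpy(dtype=object)
        finite = np.isfinite(dm.values)
        x_vals = dm.values[(arms == "X")[:, None] & finite]
        codes = ca.dose_table.matrix(gene_ids=dm.gene_ids, line_ids=dm.line_ids)
        auto_two = dm.values[((arms != "X") & ~ca.spike_mask)[:, None]
                             & (codes == 2) & finite]
        assert np.median(x_vals) <= np.median(auto_two)
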