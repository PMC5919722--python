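"""End-to-end pipeline stages shared by the analysis drivers, the CLI and
the test suite.

Each function runs one figure-style analysis on an in-memory cohort:
dose-pool delta comparisons, the resampled-median null, dosage-response
binning, and the occupancy-stratified CV comparison. ``recovery_pvalues``
bundles the four planted-effect checks used to validate the pipeline on
synthetic cohorts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose import CutoffSpec, DoseTable, assign_dose, derive_cutoff
from .expression_io import ExpressionMatrix
from .occupancy import flag_occupancy, gene_cv_table, stratified_compare
from .response import bin_vs_delta, response_table
from .synth import Cohort, CohortConfig, generate_cohort, generate_intergenic
from .variability import (
    Condition,
    GroupComparison,
    compare_groups,
    delta_matrix,
    delta_pools,
)

#: Seed offset separating the intergenic-background stream from the cohort
#: stream (both derived from one user seed, both < 2**31 for small seeds).
INTERGENIC_SEED_OFFSET = 1_000_003


def analysis_cutoff(config: CohortConfig, seed: int) -> CutoffSpec:
    """Expressed-gene cutoff for a synthetic cohort: 95th percentile of a
    freshly drawn intergenic background."""
    values = generate_intergenic(config, seed=seed + INTERGENIC_SEED_OFFSET)
    return derive_cutoff(values, percentile=95.0)


@dataclass
class CohortAnalysis:
    """A generated cohort with its dose table and expression cutoff."""

    cohort: Cohort
    dose_table: DoseTable
    cutoff: CutoffSpec
    seed: int

    @property
    def matrix(self) -> ExpressionMatrix:
        return self.cohort.matrix

    @property
    def spike_mask(self) -> np.ndarray:
        return self.matrix.genes["is_spike_in"].to_numpy(dtype=bool)

    def conditions(self) -> list[Condition]:
        cfg = self.cohort.truth.config
        return [Condition(sex=s, tissue=cfg.tissue, sex_transformed=cfg.sex_transformed)
                for s in cfg.sexes]


def prepare(config: CohortConfig, seed: int) -> CohortAnalysis:
    """Generate a cohort and derive its dose table and cutoff."""
    cohort = generate_cohort(config, seed)
    dose_table = assign_dose(cohort.matrix.genes, cohort.dfs)
    cutoff = analysis_cutoff(config, seed)
    return CohortAnalysis(cohort=cohort, dose_table=dose_table, cutoff=cutoff, seed=seed)


def dose_comparison(ca: CohortAnalysis) -> tuple[dict[str, np.ndarray], GroupComparison]:
    """Pooled one-dose vs two-dose delta comparison over all conditions."""
    pools = {"one_dose": [], "two_dose": [], "spike_in": []}
    for cond in ca.conditions():
        dm = delta_matrix(ca.matrix, cond, ca.cutoff)
        p = delta_pools(dm, ca.dose_table, spike_in=ca.spike_mask)
        for k in pools:
            pools[k].append(p[k])
    pools = {k: np.concatenate(v) for k, v in pools.items()}
    comparison = compare_groups(pools["one_dose"], pools["two_dose"],
                                label_a="one-dose", label_b="two-dose")
    return pools, comparison


def sex_comparison(ca: CohortAnalysis) -> GroupComparison:
    """Female vs male two-dose delta (overall noise difference between the
    sexes, judged on measurements unaffected by the deletions)."""
    by_sex = {}
    for cond in ca.conditions():
        dm = delta_matrix(ca.matrix, cond, ca.cutoff)
        by_sex[cond.sex] = delta_pools(dm, ca.dose_table, spike_in=ca.spike_mask)["two_dose"]
    if set(by_sex) != {"F", "M"}:
        raise ValueError("sex comparison needs both sexes in the cohort")
    return compare_groups(by_sex["F"], by_sex["M"], label_a="female", label_b="male")


def response_analysis(
    ca: CohortAnalysis, max_bin_pool: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GroupComparison]]:
    """Dosage-response bins vs delta, pooled over conditions.

    Returns (per-measurement table, per-bin summary, adjacent-bin tests).
    """
    responses, deltas = [], []
    for cond in ca.conditions():
        responses.append(response_table(ca.matrix, ca.dose_table, cond, ca.cutoff))
        deltas.append(delta_matrix(ca.matrix, cond, ca.cutoff).to_frame())
    responses = pd.concat(responses, ignore_index=True)
    deltas = pd.concat(deltas, ignore_index=True)
    summary, comparisons = bin_vs_delta(responses, deltas, max_bin_pool=max_bin_pool)
    return responses, summary, comparisons


def response_trend(
    ca: CohortAnalysis, max_bin_pool: int = 2,
) -> tuple[float, float, pd.DataFrame]:
    """Single rank trend test of delta across pooled response bins.

    The planted ordering is "delta increases with the response bin", an
    ordered alternative over the three pooled bins; a Spearman rank
    correlation of delta against the bin level tests it in one statistic
    (the adjacent-bin rank-sums of :func:`response_analysis` describe the
    same structure pairwise). Returns (rho, two-sided p, per-bin summary).
    """
    from scipy import stats

    responses, deltas = [], []
    for cond in ca.conditions():
        responses.append(response_table(ca.matrix, ca.dose_table, cond, ca.cutoff))
        deltas.append(delta_matrix(ca.matrix, cond, ca.cutoff).to_frame())
    responses = pd.concat(responses, ignore_index=True)
    deltas = pd.concat(deltas, ignore_index=True)
    merged = responses.merge(deltas[["gene_id", "line_id", "sex", "delta"]],
                             on=["gene_id", "line_id", "sex"], how="inner")
    level = np.minimum(merged["response_bin"].to_numpy(), max_bin_pool)
    rho, p = stats.spearmanr(level, merged["delta"].to_numpy())
    summary, _ = bin_vs_delta(responses, deltas, max_bin_pool=max_bin_pool)
    return float(rho), float(p), summary


def occupancy_analysis(
    ca: CohortAnalysis, exclude_arm: str | None = "2L",
) -> tuple[pd.DataFrame, pd.Series, list[GroupComparison]]:
    """Occupancy-flagged vs unflagged line-to-line CV, tested per condition.

    The female and male CV of one gene share the same line effects and are
    strongly correlated, so the sexes are tested separately rather than
    pooled into one rank-sum. Returns (CV table, flags, one comparison per
    condition).
    """
    flags = flag_occupancy(ca.matrix.genes, ca.cohort.peaks)
    tables, comparisons = [], []
    for cond in ca.conditions():
        table = gene_cv_table(ca.matrix, ca.dose_table, cond, ca.cutoff,
                              exclude_arm=exclude_arm)
        (cmp,) = stratified_compare(table, flags, flag_name=f"{cond.sex}:MOF")
        tables.append(table)
        comparisons.append(cmp)
    return pd.concat(tables, ignore_index=True), flags, comparisons


def recovery_pvalues(config: CohortConfig, seed: int) -> dict[str, dict]:
    """Run the four planted-effect checks on one synthetic cohort.

    Returns, per check, the two-sided rank-sum p-value and whether the
    medians sit in the planted direction:

    * ``dose``       — one-dose delta above two-dose delta
    * ``response``   — delta increasing across response bins 0 / 1 / >=2
      (rank trend test; direction additionally requires monotone medians)
    * ``occupancy``  — flagged CV below unflagged CV, in each sex
    * ``sex``        — female delta above male delta
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        ca = prepare(config, seed)
        _, dose_cmp = dose_comparison(ca)
        sex_cmp = sex_comparison(ca)
        trend_rho, trend_p, summary = response_trend(ca)
        _, _, occ_cmps = occupancy_analysis(ca)

    medians = summary["median_delta"].to_numpy()
    monotone = bool(len(medians) >= 2 and np.all(np.diff(medians) > 0))
    return {
        "dose": {"p": dose_cmp.p_value,
                 "direction_ok": dose_cmp.median_a > dose_cmp.median_b,
                 "median_one": dose_cmp.median_a, "median_two": dose_cmp.median_b},
        "response": {"p": trend_p, "direction_ok": monotone and trend_rho > 0,
                     "rho": trend_rho, "medians": medians.tolist()},
        "occupancy": {"p": float(max(c.p_value for c in occ_cmps)),
                      "direction_ok": all(c.median_a < c.median_b for c in occ_cmps),
                      "median_flagged": occ_cmps[0].median_a,
                      "median_unflagged": occ_cmps[0].median_b},
        "sex": {"p": sex_cmp.p_value,
                "direction_ok": sex_cmp.median_a > sex_cmp.median_b,
                "median_f": sex_cmp.median_a, "median_m": sex_cmp.median_b},
    }


def recovered_all(result: dict[str, dict], alpha: float = 0.01) -> bool:
    """True when every planted ordering is recovered at the given level."""
    return all(r["direction_ok"] and r["p"] < alpha for r in result.values())


def rejections(result: dict[str, dict], alpha: float = 0.05) -> dict[str, bool]:
    """Per-check two-sided rejection indicators (for null calibration)."""
    return {name: bool(r["p"] < alpha) for name, r in result.items()}
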