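"""Occupancy-, housekeeping- and motif-stratified expression-variability
analysis.

Across a panel of deficiency lines sharing one genetic background, the lines
in which a gene is two-dose act as replicates: the coefficient of variation
of the gene's per-line expression measures its line-to-line variability.
Genes on the deletion-bearing arm are excluded so that no measurement is
confounded by nearby deletions. CV pools are then compared between genes
overlapping chromatin-occupancy peaks (e.g. the H4K16 acetyltransferase MOF)
and the remaining genes, within strata: X-linked vs autosomal,
housekeeping (low tissue-specificity tau) vs not, EBox promoter motif
present vs absent, NSL-activated vs not.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .dose import DOSE_TWO, CutoffSpec, DoseTable
from .expression_io import ExpressionMatrix, PeakSet
from .variability import Condition, GroupComparison, compare_groups


def flag_occupancy(genes: pd.DataFrame, peaks: PeakSet) -> pd.Series:
    """True for every gene whose span overlaps >= 1 peak interval by >= 1 bp
    (half-open intervals: a peak starting exactly at a gene's end does not
    overlap). Genes without coordinates (spike-ins) are False."""
    trees: dict[str, IntervalTree] = {}
    for arm, start, end in peaks.intervals:
        trees.setdefault(arm, IntervalTree()).addi(start, end)
    flags = np.zeros(len(genes), dtype=bool)
    arms = genes["arm"].to_numpy(dtype=object)
    starts = pd.to_numeric(genes["start"], errors="coerce").to_numpy(dtype=float)
    ends = pd.to_numeric(genes["end"], errors="coerce").to_numpy(dtype=float)
    for i in range(len(genes)):
        tree = trees.get(arms[i])
        if tree is None or not np.isfinite(starts[i]):
            continue
        flags[i] = bool(tree.overlap(int(starts[i]), int(ends[i])))
    return pd.Series(flags, index=pd.Index(genes["gene_id"]), name=peaks.name)


def housekeeping_flag(tau: pd.Series, percentile: float = 5.0) -> pd.Series:
    """Housekeeping call from the tissue-specificity score tau: strictly
    below the given percentile of the observed tau distribution (broadly
    expressed genes have low tau). Genes with missing tau get NA and are
    excluded from tau-based stratifications only."""
    values = tau.dropna().to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("no tau values available")
    threshold = float(np.percentile(values, percentile))
    out = pd.Series(pd.array(tau < threshold, dtype="boolean"), index=tau.index)
    out[tau.isna()] = pd.NA
    return out


def gene_cv_table(
    matrix: ExpressionMatrix,
    dose_table: DoseTable,
    condition: Condition,
    cutoff: CutoffSpec,
    exclude_arm: str | None = "2L",
    min_lines: int = 3,
    per_line_mean: bool = True,
) -> pd.DataFrame:
    """Per-gene CV of expression across the lines where the gene is two-dose.

    Per line the replicates are averaged before the CV (``per_line_mean``,
    default); ``per_line_mean=False`` instead computes the CV over all
    individual replicate values of the usable lines. A line is usable when
    the gene passes the cutoff in all of its replicates; genes with fewer
    than ``min_lines`` usable lines are dropped with a warning, as are genes
    on ``exclude_arm`` (where the deletions reside) and spike-ins.

    Returns columns gene_id, sex, tissue, cv, n_lines.
    """
    samples = matrix.condition_samples(
        sex=condition.sex, tissue=condition.tissue,
        sex_transformed=condition.sex_transformed,
    ).sort_values(["line_id", "replicate"])
    if samples.empty:
        raise ValueError(f"no samples match condition {condition}")
    line_ids = pd.Index(samples["line_id"].unique())
    n_rep = len(samples) // len(line_ids)
    cols = matrix.sample_positions(samples["sample_id"])
    fpkm = matrix.fpkm[:, cols].reshape(matrix.shape[0], len(line_ids), n_rep)
    passing = (fpkm >= cutoff.value).all(axis=2)
    codes = dose_table.matrix(gene_ids=matrix.gene_ids, line_ids=line_ids)
    usable = passing & (codes == DOSE_TWO)

    keep_gene = np.ones(matrix.shape[0], dtype=bool)
    if "is_spike_in" in matrix.genes:
        keep_gene &= ~matrix.genes["is_spike_in"].to_numpy(dtype=bool)
    if exclude_arm is not None and "arm" in matrix.genes:
        keep_gene &= (matrix.genes["arm"] != exclude_arm).to_numpy()
    usable = usable & keep_gene[:, None]

    if per_line_mean:
        vals = fpkm.mean(axis=2)
        weight = usable.astype(float)
        n_obs = usable.sum(axis=1)
    else:
        vals = fpkm.reshape(matrix.shape[0], -1)
        weight = np.repeat(usable, n_rep, axis=1).astype(float)
        n_obs = usable.sum(axis=1) * n_rep
    n_lines = usable.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (vals * weight).sum(axis=1) / n_obs
        var = (weight * (vals - mean[:, None]) ** 2).sum(axis=1) / n_obs
        cv = np.sqrt(var) / mean

    ok = (n_lines >= min_lines) & np.isfinite(cv)
    n_dropped = int((keep_gene & ~ok & (n_lines > 0)).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} genes with fewer than {min_lines} usable "
            "two-dose lines", UserWarning, stacklevel=2,
        )
    return pd.DataFrame({
        "gene_id": matrix.gene_ids[ok],
        "sex": condition.sex,
        "tissue": condition.tissue,
        "cv": cv[ok],
        "n_lines": n_lines[ok],
    })


def stratified_compare(
    cv_records: pd.DataFrame,
    flags: pd.Series,
    strata: pd.Series | None = None,
    flag_name: str = "occupancy",
) -> list[GroupComparison]:
    """Within each stratum, rank-sum test of CV between flagged and
    unflagged genes.

    ``flags`` is a (possibly nullable) boolean Series indexed by gene_id;
    genes with NA flag are excluded. ``strata`` is a label Series indexed by
    gene_id partitioning the gene universe (default: a single stratum
    "all"); genes with NA stratum are excluded. A stratum with an empty side
    is reported with p = NaN rather than tested.
    """
    records = cv_records.set_index("gene_id")
    flags = flags.reindex(records.index)
    if strata is None:
        strata = pd.Series("all", index=records.index)
    else:
        strata = strata.reindex(records.index)
    out: list[GroupComparison] = []
    for label in pd.unique(strata.dropna()):
        in_stratum = (strata == label).fillna(False)
        defined = in_stratum & flags.notna()
        pos = records.loc[(defined & (flags == True)).to_numpy(dtype=bool), "cv"].to_numpy()
        neg = records.loc[(defined & (flags == False)).to_numpy(dtype=bool), "cv"].to_numpy()
        la = f"{label}:{flag_name}+"
        lb = f"{label}:{flag_name}-"
        if pos.size and neg.size:
            out.append(compare_groups(pos, neg, label_a=la, label_b=lb))
        else:
            out.append(GroupComparison(
                label_a=la, label_b=lb, n_a=int(pos.size), n_b=int(neg.size),
                median_a=float(np.median(pos)) if pos.size else float("nan"),
                median_b=float(np.median(neg)) if neg.size else float("nan"),
                statistic=float("nan"), p_value=float("nan"),
            ))
    return out
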