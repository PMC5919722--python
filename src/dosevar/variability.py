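"""The replicate-based variability statistic delta, CV, and group comparisons.

For a gene measured in two biological replicates with values f1, f2 the
statistic is

    delta = 2 |f1 - f2| / (f1 + f2)

i.e. the absolute replicate difference divided by the replicate mean. It is
symmetric, scale-free and bounded in [0, 2]; for a pair it equals exactly
twice the coefficient of variation under the population (divisor-n)
convention. With both replicates above a positive expression cutoff,
delta < 2 strictly.

delta is a *group-level* instrument: two replicates are far too few to
estimate the noise of an individual gene, but pooling delta over thousands of
(gene, line) measurements allows rank-sum comparisons between groups of
genes (one-dose vs two-dose, female vs male, response bins, ...). The API
therefore exposes pooled records and tests, never a per-gene noise estimate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dose import DOSE_ONE, DOSE_TWO, CutoffSpec, DoseTable
from .expression_io import ExpressionMatrix, FormatError


@dataclass(frozen=True)
class Condition:
    """A biological measurement condition: sex, tissue, sex-transformation."""

    sex: str
    tissue: str = "whole"
    sex_transformed: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")


# ----------------------------------------------------------------------
# primitives
# ----------------------------------------------------------------------

def delta(f1: float, f2: float):
    """Replicate variability 2|f1 - f2| / (f1 + f2); accepts arrays."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    total = f1 + f2
    if np.any(total <= 0):
        raise ValueError("delta requires f1 + f2 > 0 (both replicates positive)")
    out = 2.0 * np.abs(f1 - f2) / total
    return float(out) if out.ndim == 0 else out


def delta_multi(replicates: Sequence[float]) -> float:
    """Mean of delta over all unordered replicate pairs (equals
    :func:`delta` for n = 2). Used for triplicate designs."""
    values = np.asarray(list(replicates), dtype=float)
    if values.size < 2:
        raise ValueError("delta_multi needs at least two replicates")
    pairs = [delta(a, b) for a, b in combinations(values, 2)]
    return float(np.mean(pairs))


def cv(values: Sequence[float], convention: str = "population") -> float:
    """Coefficient of variation: standard deviation / mean.

    The population convention (divisor n) is the default so that the exact
    pair identity delta = 2 * CV holds; ``convention='sample'`` uses
    divisor n - 1.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty value list")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    ddof = 0 if convention == "population" else 1
    return float(arr.std(ddof=ddof) / mean)


# ----------------------------------------------------------------------
# group comparison
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """A two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two pools."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float
    p_value: float
    test: str = "wilcoxon_rank_sum"


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test between two value pools.

    Small untied inputs (both n <= 50) are tested by exact enumeration;
    otherwise the tie-corrected normal approximation is used.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        label_a=label_a, label_b=label_b,
        n_a=int(a.size), n_b=int(b.size),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        statistic=float(res.statistic), p_value=float(res.pvalue),
    )


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


# ----------------------------------------------------------------------
# cohort-level delta
# ----------------------------------------------------------------------

@dataclass
class DeltaMatrix:
    """Per-gene, per-line delta for one condition (NaN where the gene failed
    the expression filter or the line lacks the condition's replicates)."""

    gene_ids: pd.Index
    line_ids: pd.Index
    values: np.ndarray  # (n_genes, n_lines), NaN = not measured
    condition: Condition
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        g, l = np.nonzero(np.isfinite(self.values))
        return pd.DataFrame({
            "gene_id": self.gene_ids[g],
            "line_id": self.line_ids[l],
            "sex": self.condition.sex,
            "tissue": self.condition.tissue,
            "n_replicates": self.n_replicates,
            "delta": self.values[g, l],
        })


def delta_matrix(
    matrix: ExpressionMatrix,
    condition: Condition,
    cutoff: CutoffSpec,
) -> DeltaMatrix:
    """Compute delta for every (gene, line) of one condition.

    Genes must pass the cutoff in *all* of a line's replicates to be
    measured in that line. Lines with three replicates use the mean of the
    three pairwise delta values.
    """
    samples = matrix.condition_samples(
        sex=condition.sex, tissue=condition.tissue,
        sex_transformed=condition.sex_transformed,
    )
    if samples.empty:
        raise ValueError(f"no samples match condition {condition}")
    counts = samples.groupby("line_id")["sample_id"].count()
    n_rep = int(counts.iloc[0])
    if n_rep < 2:
        raise ValueError("need at least two replicates per line")
    if (counts != n_rep).any():
        bad = counts[counts != n_rep].index.tolist()
        raise FormatError(f"unequal replicate counts for lines {bad[:5]}")
    samples = samples.sort_values(["line_id", "replicate"])
    line_ids = pd.Index(samples["line_id"].unique())
    cols = matrix.sample_positions(samples["sample_id"])
    fpkm = matrix.fpkm[:, cols].reshape(matrix.shape[0], len(line_ids), n_rep)
    passing = (fpkm >= cutoff.value).all(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_deltas = [
            2.0 * np.abs(fpkm[..., i] - fpkm[..., j]) / (fpkm[..., i] + fpkm[..., j])
            for i, j in combinations(range(n_rep), 2)
        ]
        values = np.mean(pair_deltas, axis=0)
    values[~passing] = np.nan
    return DeltaMatrix(matrix.gene_ids, line_ids, values, condition, n_rep)


def delta_pools(
    dm: DeltaMatrix,
    dose_table: DoseTable,
    spike_in: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Split a delta matrix into one-dose / two-dose / spike-in pools.

    ``spike_in`` is a boolean gene mask; spike-ins are excluded from the
    dose pools and reported in their own technical-noise pool.
    """
    codes = dose_table.matrix(gene_ids=dm.gene_ids, line_ids=dm.line_ids)
    finite = np.isfinite(dm.values)
    if spike_in is None:
        spike_in = np.zeros(len(dm.gene_ids), dtype=bool)
    spike_in = np.asarray(spike_in, dtype=bool)
    genomic = ~spike_in[:, None]
    return {
        "one_dose": dm.values[(codes == DOSE_ONE) & finite & genomic],
        "two_dose": dm.values[(codes == DOSE_TWO) & finite & genomic],
        "spike_in": dm.values[spike_in[:, None] & finite],
    }


# ----------------------------------------------------------------------
# resampled null of the one-dose median
# ----------------------------------------------------------------------

@dataclass
class MedianNullResult:
    """Observed one-dose pooled delta median against a resampled two-dose null.

    Each null draw re-measures every one-dose (gene, line) observation in a
    line where the same gene is two-dose, pools those delta values, and
    records the median. ``empirical_p`` uses the add-one rule
    (1 + #{null >= observed}) / (B + 1).
    """

    observed_median: float
    null_medians: np.ndarray
    empirical_p: float
    B: int
    seed: int
    scheme: str
    n_measurements: int


def median_null(
    matrix: ExpressionMatrix,
    dose_table: DoseTable,
    condition: Condition,
    cutoff: CutoffSpec,
    B: int = 999,
    seed: int = 0,
    scheme: str = "gene",
) -> MedianNullResult:
    """Compare the pooled one-dose delta median against its two-dose null.

    ``scheme='gene'`` (default): each null draw assigns every one-dose
    measurement to a uniformly random line in which that gene is two-dose.
    ``scheme='line'``: one null median per line — the median of delta over
    the one-dose gene set measured where two-dose in that line (B is then
    the number of usable lines).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    dm = delta_matrix(matrix, condition, cutoff)
    codes = dose_table.matrix(gene_ids=dm.gene_ids, line_ids=dm.line_ids)
    finite = np.isfinite(dm.values)
    one_mask = (codes == DOSE_ONE) & finite
    two_mask = (codes == DOSE_TWO) & finite

    meas_gene, meas_line = np.nonzero(one_mask)
    cand_counts = two_mask.sum(axis=1)
    usable = cand_counts[meas_gene] > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} one-dose measurements whose gene is never "
            "two-dose elsewhere", UserWarning, stacklevel=2,
        )
    meas_gene = meas_gene[usable]
    meas_line = meas_line[usable]
    if meas_gene.size == 0:
        raise ValueError("no usable one-dose measurements")
    observed = float(np.median(dm.values[meas_gene, meas_line]))

    rng = np.random.default_rng(seed)
    if scheme == "gene":
        # flatten per-gene candidate values once; draws index into the flat array
        genes_used = np.unique(meas_gene)
        flat_vals, offsets, counts = [], {}, {}
        pos = 0
        for g in genes_used:
            vals = dm.values[g, two_mask[g]]
            flat_vals.append(vals)
            offsets[g] = pos
            counts[g] = vals.size
            pos += vals.size
        flat = np.concatenate(flat_vals)
        off = np.array([offsets[g] for g in meas_gene])
        cnt = np.array([counts[g] for g in meas_gene])
        draws = rng.integers(0, cnt, size=(B, meas_gene.size))
        null_medians = np.median(flat[off + draws], axis=1)
    elif scheme == "line":
        one_genes = np.unique(meas_gene)
        null_list = []
        for l in range(len(dm.line_ids)):
            vals = dm.values[one_genes, l][two_mask[one_genes, l]]
            if vals.size:
                null_list.append(np.median(vals))
        null_medians = np.asarray(null_list)
        B = null_medians.size
        if B == 0:
            raise ValueError("no usable lines for the line-scheme null")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    p = (1 + int((null_medians >= observed).sum())) / (B + 1)
    return MedianNullResult(
        observed_median=observed, null_medians=null_medians,
        empirical_p=float(p), B=int(B), seed=seed, scheme=scheme,
        n_measurements=int(meas_gene.size),
    )
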