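"""Dosage-response scoring for one-dose genes and its relation to delta.

Deleting one copy of a gene with no regulatory response halves its
expression: fold change FC = 0.5 against a two-dose reference. Deviation
from that halving baseline — in either direction — is a *dosage response*:

    response = | log2(FC) + 1 |

so FC = 0.5 scores 0 (no response), FC = 1 scores 1 (full compensation) and
FC = 0.25 scores 1 (anticompensation of the same magnitude). For binning,
log2(FC) is rounded to the closest integer (half-to-even) before the shift,
giving integer bins 0, 1, 2, ... The score is symmetric under reflection of
FC about the halving baseline on the log scale: FC -> 1/(4 FC) leaves it
unchanged.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .dose import DOSE_ONE, DOSE_TWO, CutoffSpec, DoseTable
from .expression_io import ExpressionMatrix
from .variability import Condition, GroupComparison, compare_groups


def response_score(fc: float, literal: bool = False):
    """Continuous response magnitude and integer bin for a fold change.

    Default reading: ``response_raw = |log2(fc) + 1|`` and
    ``response_bin = |round_half_even(log2(fc)) + 1|``. With
    ``literal=True`` the alternative reading ``|log2(FC + 1)|`` with FC
    itself rounded to the closest integer is returned for comparison (it
    does not satisfy the halving-baseline convention and is not used by the
    pipeline).
    """
    fc_arr = np.asarray(fc, dtype=float)
    if np.any(fc_arr <= 0):
        raise ValueError("fold change must be positive")
    if literal:
        raw = np.abs(np.log2(fc_arr + 1.0))
        binned = np.abs(np.log2(np.rint(fc_arr) + 1.0))
    else:
        log2fc = np.log2(fc_arr)
        raw = np.abs(log2fc + 1.0)
        binned = np.abs(np.rint(log2fc) + 1.0)
    if fc_arr.ndim == 0:
        return float(raw), (float(binned) if literal else int(binned))
    return raw, (binned if literal else binned.astype(int))


def fold_change(
    matrix: ExpressionMatrix,
    dose_table: DoseTable,
    gene_id: str,
    line_id: str,
    condition: Condition,
    cutoff: CutoffSpec,
) -> float:
    """Fold change of a one-dose gene in one line against its pooled
    two-dose reference (same sex/tissue). NaN (with a warning) when no
    two-dose reference line passes the expression filter."""
    table = response_table(matrix, dose_table, condition, cutoff,
                           genes=[gene_id], lines=[line_id])
    if table.empty:
        return float("nan")
    return float(table["fc"].iloc[0])


def response_table(
    matrix: ExpressionMatrix,
    dose_table: DoseTable,
    condition: Condition,
    cutoff: CutoffSpec,
    genes: Sequence[str] | None = None,
    lines: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per one-dose (gene, line) fold change and response score.

    Numerator: mean FPKM over the deleting line's replicates (all of which
    must pass the cutoff). Denominator: mean FPKM over the pooled replicates
    of every same-condition line in which the gene is two-dose and passes
    the cutoff in all replicates. Measurements without a usable reference
    are dropped with a warning.
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
    line_means = fpkm.mean(axis=2)

    codes = dose_table.matrix(gene_ids=matrix.gene_ids, line_ids=line_ids)
    one_mask = (codes == DOSE_ONE) & passing
    ref_mask = (codes == DOSE_TWO) & passing
    if genes is not None:
        gsel = matrix.gene_ids.isin(genes)
        one_mask &= gsel[:, None]
    if lines is not None:
        lsel = line_ids.isin(lines)
        one_mask &= lsel[None, :]

    # pooled-replicate reference mean per gene over passing two-dose lines
    ref_sum = np.where(ref_mask[..., None], fpkm, 0.0).sum(axis=(1, 2))
    ref_n = ref_mask.sum(axis=1) * n_rep
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_mean = ref_sum / ref_n

    g, l = np.nonzero(one_mask)
    has_ref = ref_n[g] > 0
    if (~has_ref).sum():
        warnings.warn(
            f"dropped {(~has_ref).sum()} one-dose measurements with no "
            "passing two-dose reference line", UserWarning, stacklevel=2,
        )
    g, l = g[has_ref], l[has_ref]
    fc = line_means[g, l] / ref_mean[g]
    raw, binned = response_score(fc) if fc.size else (np.array([]), np.array([], dtype=int))
    return pd.DataFrame({
        "gene_id": matrix.gene_ids[g],
        "line_id": line_ids[l],
        "sex": condition.sex,
        "tissue": condition.tissue,
        "fc": fc,
        "log2fc": np.log2(fc),
        "response_raw": raw,
        "response_bin": binned,
    })


def bin_vs_delta(
    responses: pd.DataFrame,
    deltas: pd.DataFrame,
    max_bin_pool: int = 2,
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Join response bins with delta and compare adjacent bins.

    Bins 0 .. max_bin_pool-1 are kept separate; bins >= max_bin_pool are
    pooled into one top bin. Returns a per-bin summary (n, median delta) and
    rank-sum comparisons between adjacent non-empty bins. Records join on
    (gene_id, line_id) and, when present in both tables, sex.
    """
    keys = ["gene_id", "line_id"] + (["sex"] if "sex" in responses and "sex" in deltas else [])
    merged = responses.merge(deltas[keys + ["delta"]], on=keys, how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["bin", "n", "median_delta"]), []
    pooled = np.minimum(merged["response_bin"].to_numpy(), max_bin_pool)
    labels = np.where(pooled >= max_bin_pool, f">={max_bin_pool}", pooled.astype(str))
    merged = merged.assign(bin=labels, bin_order=pooled)

    order = sorted(merged["bin_order"].unique())
    summary = []
    groups = {}
    for b in order:
        sub = merged.loc[merged["bin_order"] == b, "delta"].to_numpy()
        name = f">={max_bin_pool}" if b >= max_bin_pool else str(b)
        groups[b] = (name, sub)
        summary.append({"bin": name, "n": int(sub.size),
                        "median_delta": float(np.median(sub))})
    comparisons = [
        compare_groups(groups[a][1], groups[b][1],
                       label_a=f"bin {groups[a][0]}", label_b=f"bin {groups[b][0]}")
        for a, b in zip(order[:-1], order[1:])
        if groups[a][1].size and groups[b][1].size
    ]
    return pd.DataFrame(summary), comparisons
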