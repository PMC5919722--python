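"""Per-gene, per-line dose assignment and the expressed-gene cutoff.

A gene is *one-dose* in a deficiency line when its span lies entirely inside
the line's deleted interval (heterozygous deletion leaves a single copy),
*two-dose* when it does not overlap the deletion at all, and *excluded* when
it straddles a deletion breakpoint — a boundary gene may be physically
truncated, so it is kept out of both dose groups in that line.

The expression cutoff separates genes from intergenic background signal: a
gene counts as expressed in a comparison group only when every replicate is
at or above the cutoff (linear FPKM scale).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression_io import DfDefinition, ExpressionMatrix

#: FPKM cutoff derived from intergenic signal in the published DrosDel
#: whole-fly tables; use with ``CutoffSpec(..., method="fixed")`` when
#: analysing those tables rather than a synthetic cohort.
REFERENCE_FPKM_CUTOFF = 0.6829118

DOSE_EXCLUDED = 0
DOSE_ONE = 1
DOSE_TWO = 2


@dataclass(frozen=True)
class CutoffSpec:
    """An expressed-gene FPKM threshold and how it was obtained."""

    value: float
    method: str = "intergenic_percentile"  # or "fixed", "median_top_tail"
    percentile: float = 95.0

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"cutoff must be positive, got {self.value}")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")


def fixed_cutoff(value: float) -> CutoffSpec:
    return CutoffSpec(value=value, method="fixed")


def derive_cutoff(
    intergenic_fpkm: Iterable[float],
    percentile: float = 95.0,
    method: str = "percentile",
) -> CutoffSpec:
    """Derive the expressed-gene cutoff from intergenic background signal.

    ``method='percentile'`` (default) takes the given percentile of the
    intergenic distribution with linear interpolation. ``method='median_top_tail'``
    takes the median of the values at or above that percentile — the other
    reading of "median of the top tail"; both are exposed.
    """
    values = np.asarray(list(intergenic_fpkm), dtype=float)
    if values.size == 0:
        raise ValueError("empty intergenic signal list")
    if (values < 0).any():
        raise ValueError("negative intergenic signal")
    if method == "percentile":
        cut = float(np.percentile(values, percentile))
    elif method == "median_top_tail":
        tail = values[values >= np.percentile(values, percentile)]
        cut = float(np.median(tail))
    else:
        raise ValueError(f"unknown cutoff method {method!r}")
    return CutoffSpec(value=cut, method=method if method != "percentile" else "intergenic_percentile",
                      percentile=percentile)


class DoseTable:
    """Dense per-gene, per-line dose codes (1, 2, or excluded)."""

    def __init__(self, gene_ids: pd.Index, line_ids: pd.Index, codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(gene_ids), len(line_ids)):
            raise ValueError("dose code matrix shape mismatch")
        self.gene_ids = pd.Index(gene_ids)
        self.line_ids = pd.Index(line_ids)
        self.codes = codes

    def dose(self, gene_id: str, line_id: str) -> int | str:
        g = self.gene_ids.get_loc(gene_id)
        l = self.line_ids.get_loc(line_id)
        code = int(self.codes[g, l])
        return "excluded" if code == DOSE_EXCLUDED else code

    def matrix(self, gene_ids: Sequence[str] | None = None,
               line_ids: Sequence[str] | None = None) -> np.ndarray:
        """Dose codes reindexed to the requested gene/line order.

        Lines without a recorded deletion carry no Df, so their column is
        all two-dose."""
        codes = self.codes
        if gene_ids is not None:
            pos = self.gene_ids.get_indexer(list(gene_ids))
            if (pos < 0).any():
                raise KeyError("unknown gene_id in dose table reindex")
            codes = codes[pos]
        if line_ids is not None:
            pos = self.line_ids.get_indexer(list(line_ids))
            out = np.full((codes.shape[0], len(pos)), DOSE_TWO, dtype=np.int8)
            known = pos >= 0
            out[:, known] = codes[:, pos[known]]
            codes = out
        return codes

    def one_dose_genes(self, line_id: str) -> pd.Index:
        l = self.line_ids.get_loc(line_id)
        return self.gene_ids[self.codes[:, l] == DOSE_ONE]

    def to_frame(self, full: bool = False) -> pd.DataFrame:
        """Long-format table ``gene_id, line_id, dose``. By default only
        non-two-dose entries are emitted (two-dose is the overwhelming
        default state)."""
        g, l = np.nonzero(self.codes != DOSE_TWO) if not full else np.indices(self.codes.shape).reshape(2, -1)
        dose = self.codes[g, l]
        labels = np.where(dose == DOSE_EXCLUDED, "excluded", dose.astype(str))
        return pd.DataFrame({
            "gene_id": self.gene_ids[g],
            "line_id": self.line_ids[l],
            "dose": labels,
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, gene_ids: Sequence[str],
                   line_ids: Sequence[str]) -> "DoseTable":
        gene_ids = pd.Index(gene_ids)
        line_ids = pd.Index(line_ids)
        codes = np.full((len(gene_ids), len(line_ids)), DOSE_TWO, dtype=np.int8)
        g = gene_ids.get_indexer(frame["gene_id"])
        l = line_ids.get_indexer(frame["line_id"])
        if (g < 0).any() or (l < 0).any():
            raise KeyError("dose frame refers to unknown gene or line")
        val = frame["dose"].astype(str).map({"1": DOSE_ONE, "2": DOSE_TWO, "excluded": DOSE_EXCLUDED})
        if val.isna().any():
            raise ValueError("dose values must be 1, 2 or 'excluded'")
        codes[g, l] = val.to_numpy(dtype=np.int8)
        return cls(gene_ids, line_ids, codes)


def assign_dose(genes: pd.DataFrame, dfs: Sequence[DfDefinition]) -> DoseTable:
    """Assign per-gene, per-line dose from deletion intervals.

    dose(g, line) = 1 iff [start_g, end_g) is contained in the line's deleted
    interval on the same arm; 2 iff the gene does not overlap the deletion;
    excluded iff it partially overlaps. Genes without genomic coordinates
    (spike-ins) are two-dose everywhere. Result is independent of the input
    ordering of genes and lines (codes are aligned to the given orders).
    """
    gene_ids = pd.Index(genes["gene_id"])
    line_ids = pd.Index([d.line_id for d in dfs])
    if line_ids.duplicated().any():
        raise ValueError("duplicate Df line_id")
    codes = np.full((len(gene_ids), len(line_ids)), DOSE_TWO, dtype=np.int8)
    arm = genes["arm"].astype("string").fillna("").to_numpy(dtype=object)
    start = pd.to_numeric(genes["start"], errors="coerce").to_numpy(dtype=float)
    end = pd.to_numeric(genes["end"], errors="coerce").to_numpy(dtype=float)
    genomic = ~genes["is_spike_in"].to_numpy(dtype=bool) if "is_spike_in" in genes else np.ones(len(genes), bool)
    for j, d in enumerate(dfs):
        on_arm = genomic & (arm == d.arm)
        if not on_arm.any():
            continue
        overlaps = on_arm & (start < d.end) & (end > d.start)
        contained = overlaps & (start >= d.start) & (end <= d.end)
        codes[contained, j] = DOSE_ONE
        codes[overlaps & ~contained, j] = DOSE_EXCLUDED
    return DoseTable(gene_ids, line_ids, codes)


def filter_expressed(
    matrix: ExpressionMatrix,
    sample_ids: Sequence[str],
    cutoff: CutoffSpec,
) -> pd.Index:
    """Genes whose FPKM is at or above the cutoff in *every* named sample."""
    cols = matrix.sample_positions(sample_ids)
    if cols.size == 0:
        raise ValueError("empty sample set")
    keep = (matrix.fpkm[:, cols] >= cutoff.value).all(axis=1)
    return matrix.gene_ids[keep]
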