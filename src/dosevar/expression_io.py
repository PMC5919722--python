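"""Readers, writers and in-memory containers for the cohort file formats.

Expression is carried as a dense genes x samples matrix of linear-scale FPKM
values with two metadata tables: a gene annotation (chromosome arm,
coordinates, tissue-specificity tau, promoter-motif and occupancy flags) and a
sample sheet (deficiency line, sex, sex-transformation status, tissue,
replicate number).

Every genomic interval in the package — gene spans, deletion intervals,
occupancy peaks — follows the BED convention: 0-based, half-open.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Chromosome arms of the Drosophila melanogaster nuclear genome.
ARMS = ("2L", "2R", "3L", "3R", "4", "X")

ANNOTATION_COLUMNS = [
    "gene_id", "arm", "start", "end",
    "tau", "ebox", "nsl_activated", "is_spike_in",
]
SAMPLE_COLUMNS = [
    "sample_id", "line_id", "sex", "sex_transformed", "tissue", "replicate",
]


class FormatError(ValueError):
    """A malformed input file or structurally inconsistent table."""


@dataclass(frozen=True)
class DfDefinition:
    """A deficiency (Df) line: one engineered deletion interval.

    Flies heterozygous for the Df carry a single dose of every gene that lies
    entirely inside ``[start, end)`` on ``arm``.
    """

    line_id: str
    arm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise FormatError(f"unknown chromosome arm {self.arm!r}")
        if not self.start < self.end:
            raise FormatError(
                f"inverted interval [{self.start}, {self.end}) for {self.line_id}"
            )


@dataclass(frozen=True)
class PeakSet:
    """A named set of occupancy intervals (e.g. MOF ChIP peaks)."""

    name: str
    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for arm, start, end in self.intervals:
            if arm not in ARMS:
                raise FormatError(f"unknown chromosome arm {arm!r} in peak set")
            if not start < end:
                raise FormatError(f"inverted peak interval [{start}, {end}) on {arm}")


class ExpressionMatrix:
    """Dense genes x samples FPKM matrix with aligned metadata.

    Parameters
    ----------
    genes
        DataFrame with at least a unique ``gene_id`` column; may carry the
        full annotation (arm, start, end, tau, ebox, nsl_activated,
        is_spike_in).
    samples
        DataFrame with the columns of :data:`SAMPLE_COLUMNS`;
        ``(line_id, sex, sex_transformed, tissue, replicate)`` must be unique.
    fpkm
        ``(n_genes, n_samples)`` array of non-negative finite linear FPKM.
    """

    def __init__(self, genes: pd.DataFrame, samples: pd.DataFrame, fpkm: np.ndarray):
        genes = genes.reset_index(drop=True)
        samples = samples.reset_index(drop=True)
        fpkm = np.asarray(fpkm, dtype=float)
        if fpkm.ndim != 2 or fpkm.shape != (len(genes), len(samples)):
            raise FormatError(
                f"FPKM shape {fpkm.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if genes["gene_id"].duplicated().any():
            dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene_id {dup!r}")
        if samples["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in metadata")
        key_cols = ["line_id", "sex", "sex_transformed", "tissue", "replicate"]
        if set(key_cols) <= set(samples.columns) and samples[key_cols].duplicated().any():
            raise FormatError("duplicate (line, sex, sex_transformed, tissue, replicate) key")
        if not np.isfinite(fpkm).all():
            raise ValueError("non-finite FPKM value")
        if (fpkm < 0).any():
            raise ValueError("negative FPKM value")
        self.genes = genes
        self.samples = samples
        self.fpkm = fpkm

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.samples["sample_id"])

    @property
    def shape(self) -> tuple[int, int]:
        return self.fpkm.shape

    def attach_annotation(self, annotation: pd.DataFrame) -> "ExpressionMatrix":
        """Return a copy whose gene table is the given annotation, reordered
        to this matrix's gene order. Every gene must be annotated."""
        ann = annotation.set_index("gene_id")
        missing = self.gene_ids.difference(ann.index)
        if len(missing):
            raise FormatError(f"{len(missing)} genes missing from annotation, e.g. {missing[0]!r}")
        genes = ann.loc[self.gene_ids].reset_index()
        return ExpressionMatrix(genes, self.samples.copy(), self.fpkm)

    def sample_positions(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Column positions of the named samples (KeyError if unknown)."""
        lookup = pd.Index(self.samples["sample_id"])
        pos = lookup.get_indexer(list(sample_ids))
        if (pos < 0).any():
            bad = np.asarray(sample_ids)[pos < 0][0]
            raise KeyError(f"unknown sample {bad!r}")
        return pos

    def condition_samples(
        self,
        sex: str | None = None,
        tissue: str | None = None,
        sex_transformed: bool | None = None,
    ) -> pd.DataFrame:
        """Sample metadata rows matching the given condition filters."""
        s = self.samples
        mask = np.ones(len(s), dtype=bool)
        if sex is not None:
            mask &= (s["sex"] == sex).to_numpy()
        if tissue is not None:
            mask &= (s["tissue"] == tissue).to_numpy()
        if sex_transformed is not None:
            mask &= (s["sex_transformed"] == sex_transformed).to_numpy()
        return s.loc[mask]


# ----------------------------------------------------------------------
# expression + sample sheet
# ----------------------------------------------------------------------

def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV (columns of :data:`SAMPLE_COLUMNS`)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "line_id": str}, comment="#")
    missing = [c for c in SAMPLE_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns {missing}")
    meta["sex_transformed"] = meta["sex_transformed"].astype(bool)
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["replicate"] < 1).any():
        raise FormatError("replicate numbers must be positive")
    if not meta["sex"].isin(["F", "M"]).all():
        raise FormatError("sex must be F or M")
    return meta[SAMPLE_COLUMNS]


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read an FPKM table (first column ``gene_id``, one column per sample)
    together with its sample sheet, and validate both."""
    table = pd.read_csv(path, sep="\t", comment="#")
    if table.columns[0] != "gene_id":
        raise FormatError("first column of an expression table must be 'gene_id'")
    meta = read_samples(metadata_path)
    sample_cols = list(table.columns[1:])
    if set(sample_cols) != set(meta["sample_id"]):
        unknown = sorted(set(sample_cols) ^ set(meta["sample_id"]))
        raise FormatError(f"expression columns and sample sheet disagree: {unknown[:5]}")
    try:
        values = table[sample_cols].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric FPKM value: {exc}") from exc
    genes = table[["gene_id"]].astype(str)
    meta = meta.set_index("sample_id").loc[sample_cols].reset_index()
    return ExpressionMatrix(genes, meta, values)


def write_expression(
    matrix: ExpressionMatrix,
    path: str | Path,
    metadata_path: str | Path | None = None,
    float_format: str = "%.8g",
) -> None:
    """Write an :class:`ExpressionMatrix` back to TSV (values kept to >= 6
    significant digits so a read/write round trip is value-preserving)."""
    table = pd.DataFrame(matrix.fpkm, columns=matrix.sample_ids)
    table.insert(0, "gene_id", matrix.gene_ids)
    table.to_csv(path, sep="\t", index=False, float_format=float_format)
    if metadata_path is not None:
        matrix.samples[SAMPLE_COLUMNS].to_csv(metadata_path, sep="\t", index=False)


# ----------------------------------------------------------------------
# annotation
# ----------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read and validate a gene annotation TSV.

    ``tau``, ``ebox`` and ``nsl_activated`` may be missing per gene; a missing
    value excludes the gene from the corresponding stratified analysis only.
    Spike-in rows (``is_spike_in`` true) have no genomic coordinates.
    """
    ann = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation missing columns {missing}")
    ann = ann[ANNOTATION_COLUMNS].copy()
    ann["is_spike_in"] = ann["is_spike_in"].astype(bool)
    if ann["gene_id"].duplicated().any():
        raise FormatError("duplicate gene_id in annotation")
    genomic = ~ann["is_spike_in"]
    if not ann.loc[genomic, "arm"].isin(ARMS).all():
        bad = ann.loc[genomic & ~ann["arm"].isin(ARMS), "arm"].iloc[0]
        raise FormatError(f"unknown chromosome arm {bad!r}")
    coords = ann.loc[genomic, ["start", "end"]]
    if coords.isna().any().any():
        raise FormatError("genomic gene with missing coordinates")
    if not (coords["start"] < coords["end"]).all():
        raise FormatError("gene with start >= end")
    tau = ann["tau"].dropna()
    if len(tau) and not ((tau >= 0) & (tau <= 1)).all():
        raise FormatError("tau outside [0, 1]")
    return ann


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.8g")


# ----------------------------------------------------------------------
# intervals (BED)
# ----------------------------------------------------------------------

def read_intervals(path: str | Path, kind: str, name: str | None = None):
    """Read a BED3/BED4 file of genomic intervals (0-based, half-open).

    ``kind='df'`` requires a name column (the deficiency line id) and returns
    a list of :class:`DfDefinition`; ``kind='peak'`` returns a
    :class:`PeakSet` named ``name`` (default: the file stem).
    """
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            arm = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if arm not in ARMS:
                raise FormatError(f"{path}:{lineno}: unknown chromosome arm {arm!r}")
            if not start < end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            label = fields[3] if len(fields) > 3 else None
            rows.append((arm, start, end, label))
    if kind == "df":
        if any(label is None for *_, label in rows):
            raise FormatError("Df intervals require a BED name column (line_id)")
        dfs = [DfDefinition(label, arm, start, end) for arm, start, end, label in rows]
        seen: set[str] = set()
        for d in dfs:
            if d.line_id in seen:
                raise FormatError(f"duplicate Df line_id {d.line_id!r}")
            seen.add(d.line_id)
        return dfs
    if kind == "peak":
        peak_name = name or Path(path).stem
        return PeakSet(peak_name, tuple((a, s, e) for a, s, e, _ in rows))
    raise ValueError(f"kind must be 'df' or 'peak', got {kind!r}")


def write_intervals(obj: Iterable[DfDefinition] | PeakSet, path: str | Path) -> None:
    """Write Df definitions or a peak set as BED4/BED3."""
    with open(path, "w") as handle:
        if isinstance(obj, PeakSet):
            for arm, start, end in obj.intervals:
                handle.write(f"{arm}\t{start}\t{end}\t{obj.name}\n")
        else:
            for d in obj:
                handle.write(f"{d.arm}\t{d.start}\t{d.end}\t{d.line_id}\n")
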