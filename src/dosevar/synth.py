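"""Synthetic deficiency-line cohort generator with planted ground truth.

The generator emulates the statistical structure of a sexed deficiency-line
RNA-seq panel so that every stage of the analysis is testable without any
download: ~99 lines each deleting ~40 contiguous genes on one arm, two
replicates per line per sex (three for the head preset), log-normal baseline
expression, halved expression plus a gene-specific regulatory response for
one-dose genes, noise inflation for one-dose genes that grows with the
response magnitude, reduced noise for occupancy-flagged genes, a female
noise multiplier, low-noise spike-ins, and a long-tailed intergenic
background for the expression cutoff.

Generative model (log2 scale, so all planted effects are multiplicative and
visible to the scale-free statistics downstream):

    log2 FPKM[g, line, rep] = log2 B_g + dose_term + eps_line + eps_rep

* ``B_g``: log-normal baseline, log2 B_g ~ Normal(baseline_log2_mean, sd).
* ``dose_term`` = 0 for two-dose; -1 + rho_g for one-dose, with the signed
  dosage response rho_g ~ Normal(0, sigma_rho) — rho = 0 is pure halving,
  rho = 1 full compensation, rho < 0 anticompensation. The response
  magnitude the pipeline recovers is |log2(FC) + 1| = |rho_g|.
* ``eps_line`` ~ Normal(0, line_sd * kappa_line) per (gene, line), shared by
  sexes and replicates of that line.
* ``eps_rep`` ~ Normal(0, replicate_sd * kappa_rep) per sample.

The noise multipliers carry the planted effects. One-dose measurements are
inflated by kappa = 1 + alpha0 + alpha1 * |rho_g| (regulation induced by
dose reduction is itself noisy, the more so the stronger the response);
the inflation applies to both the line and the replicate component.
Occupancy-flagged genes have both components shrunk by m < 1 in every line
(chromatin-based noise dampening). Female samples get ``female_noise`` on
the replicate component. Under male-X compensation, X genes in males keep
dose term 0 and a replicate-noise factor <= 1.

Spike-ins are constant across samples up to a small technical noise and
carry no biological effects.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .expression_io import ARMS, DfDefinition, ExpressionMatrix, PeakSet

GENE_LENGTH = 2000
GENE_SPACING = 3000  # start-to-start; leaves a 1 kb gap between genes
DF_MARGIN = 500      # deletion breakpoints fall inside the intergenic gap


def _default_arms() -> dict[str, int]:
    # Gene counts proportioned like the fly nuclear arms.
    return {"2L": 2200, "2R": 2400, "3L": 2400, "3R": 2800, "X": 1900, "4": 100}


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; the defaults are the study conditions."""

    arms: Mapping[str, int] = field(default_factory=_default_arms)
    df_arm: str = "2L"
    n_df_lines: int = 99
    genes_per_df: int = 40
    replicates: int = 2
    sexes: tuple[str, ...] = ("F", "M")
    tissue: str = "whole"
    sex_transformed: bool = False
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    replicate_sd: float = 0.25    # log2 units
    line_sd: float = 0.35         # log2 units
    alpha0: float = 0.5           # base one-dose noise inflation
    alpha1: float = 1.0           # inflation per unit |response|
    sigma_rho: float = 1.0        # sd of the signed dosage response
    occupancy_fraction: float = 0.25
    occupancy_shrink: float = 0.6  # m < 1: noise factor for flagged genes
    ebox_fraction: float = 0.3
    nsl_fraction: float = 0.4
    female_noise: float = 1.3
    male_x_compensation: bool = True
    male_x_noise: float = 0.8
    spike_in_count: int = 92
    spike_in_log2_mean: float = 4.0
    spike_in_sd: float = 0.05     # technical noise, log2 units
    n_intergenic: int = 3000
    intergenic_log2_mean: float = -3.0
    intergenic_log2_sd: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.df_arm not in self.arms:
            raise ValueError(f"df_arm {self.df_arm!r} not among arms")
        if self.genes_per_df > self.arms[self.df_arm]:
            raise ValueError("genes_per_df exceeds the number of genes on the Df arm")
        for name in ("replicate_sd", "line_sd", "sigma_rho", "spike_in_sd",
                     "intergenic_log2_sd", "alpha0", "alpha1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.occupancy_shrink <= 1:
            raise ValueError("occupancy_shrink must be in (0, 1]")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        for a in self.arms:
            if a not in ARMS:
                raise ValueError(f"unknown arm {a!r}")

    def null(self) -> "CohortConfig":
        """The same cohort with every planted noise effect switched off
        (dose still halves expression and responses still shift means)."""
        return replace(self, alpha0=0.0, alpha1=0.0, occupancy_shrink=1.0,
                       female_noise=1.0, male_x_noise=1.0)

    @property
    def n_genes(self) -> int:
        return int(sum(self.arms.values()))


def head_config(**overrides) -> CohortConfig:
    """Triplicate head-tissue preset: X-chromosome deletion panel."""
    base = dict(df_arm="X", n_df_lines=30, replicates=3, tissue="head")
    base.update(overrides)
    return CohortConfig(**base)


@dataclass
class SyntheticTruth:
    """Planted per-gene and per-line parameters behind a generated cohort."""

    genes: pd.DataFrame   # gene_id, baseline_log2, rho, inflation, occupancy, tau, ebox, nsl_activated, housekeeping
    lines: pd.DataFrame   # line_id, arm, start, end, first_gene, n_genes
    config: CohortConfig


@dataclass
class Cohort:
    matrix: ExpressionMatrix
    dfs: list[DfDefinition]
    peaks: PeakSet
    truth: SyntheticTruth


def _gene_coordinates(arms: Mapping[str, int]) -> pd.DataFrame:
    rows = []
    for arm in sorted(arms):
        for i in range(arms[arm]):
            start = i * GENE_SPACING
            rows.append((f"G{arm}_{i:05d}", arm, start, start + GENE_LENGTH))
    return pd.DataFrame(rows, columns=["gene_id", "arm", "start", "end"])


def generate_cohort(config: CohortConfig, seed: int | None = None) -> Cohort:
    """Draw a full cohort (expression + annotation + deletions + peaks) and
    its ground truth. Bit-identical for a fixed seed."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    genes = _gene_coordinates(config.arms)
    G = len(genes)
    arm = genes["arm"].to_numpy(dtype=object)
    is_x = arm == "X"

    # planted per-gene parameters
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, G)
    rho = rng.normal(0.0, config.sigma_rho, G)
    occupancy = rng.random(G) < config.occupancy_fraction
    tau = rng.random(G)
    ebox = rng.random(G) < config.ebox_fraction
    nsl = rng.random(G) < config.nsl_fraction
    inflation = 1.0 + config.alpha0 + config.alpha1 * np.abs(rho)

    # deletion lines: contiguous blocks of genes on the Df arm
    arm_positions = np.flatnonzero(arm == config.df_arm)
    n_arm = arm_positions.size
    first = rng.integers(0, n_arm - config.genes_per_df + 1, config.n_df_lines)
    line_ids = [f"Df{i + 1:03d}" for i in range(config.n_df_lines)]
    dfs, line_rows = [], []
    one_dose = np.zeros((G, config.n_df_lines), dtype=bool)
    for j, (lid, f0) in enumerate(zip(line_ids, first)):
        block = arm_positions[f0:f0 + config.genes_per_df]
        start = int(genes.loc[block[0], "start"] - DF_MARGIN)
        end = int(genes.loc[block[-1], "end"] + DF_MARGIN)
        dfs.append(DfDefinition(lid, config.df_arm, max(start, 0), end))
        one_dose[block, j] = True
        line_rows.append((lid, config.df_arm, max(start, 0), end, int(f0), config.genes_per_df))

    # occupancy peaks: one interval inside each flagged gene's span
    flagged = genes.loc[occupancy]
    peaks = PeakSet("MOF", tuple(
        (str(r.arm), int(r.start) + 100, int(r.end) - 100)
        for r in flagged.itertuples()
    ))

    # samples
    sample_rows = []
    for lid in line_ids:
        for sex in config.sexes:
            for rep in range(1, config.replicates + 1):
                sample_rows.append((f"{lid}_{sex}_r{rep}", lid, sex,
                                    config.sex_transformed, config.tissue, rep))
    samples = pd.DataFrame(sample_rows, columns=[
        "sample_id", "line_id", "sex", "sex_transformed", "tissue", "replicate"])
    S = len(samples)
    line_idx = pd.Index(line_ids).get_indexer(samples["line_id"])
    is_f = (samples["sex"] == "F").to_numpy()
    is_m_sample = ~is_f if not config.sex_transformed else np.zeros(S, bool)
    # phenotypic males (XY); sex-transformed XX flies stay two-dose on X
    male_x = is_x[:, None] & is_m_sample[None, :]

    occ_factor = np.where(occupancy, config.occupancy_shrink, 1.0)

    # line effects, shared across sexes/replicates of a line
    kappa_line = occ_factor[:, None] * np.where(one_dose, inflation[:, None], 1.0)
    eps_line = rng.standard_normal((G, config.n_df_lines)) * config.line_sd * kappa_line

    # replicate effects
    one_dose_s = one_dose[:, line_idx]
    kappa_rep = occ_factor[:, None] * np.where(one_dose_s, inflation[:, None], 1.0)
    kappa_rep = kappa_rep * np.where(is_f[None, :], config.female_noise, 1.0)
    if config.male_x_compensation:
        kappa_rep = kappa_rep * np.where(male_x, config.male_x_noise, 1.0)
    eps_rep = rng.standard_normal((G, S)) * config.replicate_sd * kappa_rep

    dose_term = np.where(one_dose_s, -1.0 + rho[:, None], 0.0)
    if not config.male_x_compensation:
        # uncompensated single male X: halved expression, ordinary inflation
        dose_term = np.where(male_x & ~one_dose_s, -1.0, dose_term)

    log2_fpkm = baseline[:, None] + dose_term + eps_line[:, line_idx] + eps_rep
    fpkm = np.exp2(log2_fpkm)

    # spike-ins: technical noise only
    n_spike = config.spike_in_count
    spike_base = rng.normal(config.spike_in_log2_mean, 1.0, n_spike)
    spike = np.exp2(spike_base[:, None] + rng.standard_normal((n_spike, S)) * config.spike_in_sd)
    spike_ids = [f"SPIKE_{i + 1:03d}" for i in range(n_spike)]

    annotation = pd.DataFrame({
        "gene_id": list(genes["gene_id"]) + spike_ids,
        "arm": list(genes["arm"]) + [pd.NA] * n_spike,
        "start": list(genes["start"]) + [pd.NA] * n_spike,
        "end": list(genes["end"]) + [pd.NA] * n_spike,
        "tau": list(tau) + [np.nan] * n_spike,
        "ebox": list(ebox) + [pd.NA] * n_spike,
        "nsl_activated": list(nsl) + [pd.NA] * n_spike,
        "is_spike_in": [False] * G + [True] * n_spike,
    })
    matrix = ExpressionMatrix(annotation, samples, np.vstack([fpkm, spike]))

    hk_threshold = np.percentile(tau, 5.0)
    truth_genes = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "arm": genes["arm"],
        "baseline_log2": baseline,
        "rho": rho,
        "inflation": inflation,
        "occupancy": occupancy,
        "tau": tau,
        "ebox": ebox,
        "nsl_activated": nsl,
        "housekeeping": tau < hk_threshold,
    })
    truth = SyntheticTruth(
        genes=truth_genes,
        lines=pd.DataFrame(line_rows, columns=["line_id", "arm", "start", "end",
                                               "first_gene", "n_genes"]),
        config=replace(config, seed=seed),
    )
    return Cohort(matrix=matrix, dfs=dfs, peaks=peaks, truth=truth)


def generate_intergenic(config: CohortConfig, seed: int | None = None) -> np.ndarray:
    """Log-normal intergenic background signals (low mean, long tail).

    The true quantile is available in closed form:
    ``intergenic_quantile(config, q)``; an empirical 95th-percentile cutoff
    derived from a large draw converges to it.
    """
    if config.n_intergenic < 1:
        raise ValueError("n_intergenic must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    draws = rng.normal(config.intergenic_log2_mean, config.intergenic_log2_sd,
                       config.n_intergenic)
    return np.exp2(draws)


def intergenic_quantile(config: CohortConfig, q: float = 95.0) -> float:
    """Closed-form quantile of the intergenic log-normal distribution."""
    from scipy.stats import norm

    z = norm.ppf(q / 100.0)
    return float(2.0 ** (config.intergenic_log2_mean + z * config.intergenic_log2_sd))
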