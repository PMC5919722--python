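"""Exact stochastic simulation of the two-state (telegraph) promoter model.

Each gene copy switches spontaneously between a repressed (OFF) and an
active (ON) state with first-order rates k_on (activation) and k_off
(repression). While ON it produces mRNA at rate s_a; every mRNA molecule
decays at rate delta_m. Two gene copies are simulated as independent
reaction channels inside one exact SSA (equivalent to, and faster than, two
separate simulations). All simulations start with every copy OFF and zero
mRNA.

Closed forms for the stationary distribution serve as independent oracles:

    mean = n_copies * k_on / (k_on + k_off) * s_a / delta_m
    Fano = 1 + s_a * k_off / ((k_on + k_off) * (k_on + k_off + delta_m))

(the Fano factor is identical for one and two independent copies).

The population-level experiment mirrors a two-replicate RNA-seq measurement:
average the mRNA count of N independent cells at one observation time, do it
twice with fresh randomness, and take delta of the two population means. By
the central limit theorem the mean delta shrinks like N^(-1/2) — single-cell
(gene-intrinsic) noise averages out in the cell populations of a whole
organism.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .variability import delta as _delta


@dataclass(frozen=True)
class TelegraphParams:
    """Rates (per second) of the ON-OFF transcription model."""

    k_on: float
    k_off: float
    s_a: float
    delta_m: float
    n_copies: int = 1

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "s_a", "delta_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_copies not in (1, 2):
            raise ValueError("n_copies must be 1 or 2")

    def with_copies(self, n_copies: int) -> "TelegraphParams":
        return replace(self, n_copies=n_copies)


def half_life(rate: float) -> float:
    """Half-time (seconds) of a first-order process: ln 2 / rate."""
    if not rate > 0:
        raise ValueError("rate must be positive")
    return math.log(2.0) / rate


def rate_from_half_life(t_half: float) -> float:
    """First-order rate (/sec) with the given half-time in seconds."""
    if not t_half > 0:
        raise ValueError("half-time must be positive")
    return math.log(2.0) / t_half


#: Default bursty-promoter regime: symmetric switching at 0.02/s (35 s
#: half-time), transcription 0.01/s while active, mRNA decay 0.008/s.
ONE_DOSE = TelegraphParams(k_on=0.02, k_off=0.02, s_a=0.01, delta_m=0.008, n_copies=1)
#: One copy transcribing at twice the rate — per-copy (compensated) output
#: matching the two-copy total.
ONE_DOSE_COMPENSATED = TelegraphParams(k_on=0.02, k_off=0.02, s_a=0.02, delta_m=0.008, n_copies=1)
TWO_DOSE = TelegraphParams(k_on=0.02, k_off=0.02, s_a=0.01, delta_m=0.008, n_copies=2)
#: Alternative decay preset: rate implied by a 14-minute mRNA half-life.
DELTA_M_14MIN = rate_from_half_life(14 * 60.0)


def stationary_mean(params: TelegraphParams) -> float:
    """Closed-form stationary mean mRNA count."""
    p_on = params.k_on / (params.k_on + params.k_off)
    return params.n_copies * p_on * params.s_a / params.delta_m


def fano_factor(params: TelegraphParams) -> float:
    """Closed-form stationary Fano factor (variance / mean); independent of
    copy number for independent copies, and -> 1 in the constitutive limit
    k_off -> 0."""
    k_sum = params.k_on + params.k_off
    return 1.0 + params.s_a * params.k_off / (k_sum * (k_sum + params.delta_m))


def default_t_obs(params: TelegraphParams, multiple: float = 5.0) -> float:
    """Default observation time: a burn-in of ``multiple`` mRNA lifetimes."""
    return multiple / params.delta_m


# ----------------------------------------------------------------------
# single-cell trajectory
# ----------------------------------------------------------------------

@dataclass
class SimTrajectory:
    """One cell's exact SSA trajectory: event times, total mRNA after each
    event, and per-copy promoter states."""

    times: np.ndarray
    mrna: np.ndarray
    promoter_on: np.ndarray  # (n_events + 1, n_copies) bool

    def count_at(self, t: float) -> int:
        """Total mRNA at time t (state is piecewise constant)."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return int(self.mrna[max(idx, 0)])


def simulate_cell(params: TelegraphParams, t_end: float, seed) -> SimTrajectory:
    """Exact Gillespie simulation of one cell up to ``t_end`` seconds.

    Reactions: OFF_i -> ON_i (k_on), ON_i -> OFF_i (k_off),
    ON_i: 0 -> mRNA (s_a), mRNA -> 0 (delta_m * count). Deterministic given
    the seed.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(seed)
    n = params.n_copies
    on = [False] * n
    m = 0
    t = 0.0
    times = [0.0]
    counts = [0]
    states = [tuple(on)]
    while True:
        copy_rates = [params.k_off if s else params.k_on for s in on]
        prod = params.s_a * sum(on)
        deg = params.delta_m * m
        total = sum(copy_rates) + prod + deg
        t += rng.exponential(1.0 / total)
        if t > t_end:
            break
        u = rng.random() * total
        acc = 0.0
        for i, r in enumerate(copy_rates):
            acc += r
            if u < acc:
                on[i] = not on[i]
                break
        else:
            if u < acc + prod:
                m += 1
            else:
                m -= 1
        times.append(t)
        counts.append(m)
        states.append(tuple(on))
    return SimTrajectory(
        times=np.asarray(times), mrna=np.asarray(counts),
        promoter_on=np.asarray(states, dtype=bool).reshape(len(times), n),
    )


# ----------------------------------------------------------------------
# cell populations (vectorized exact SSA, final state only)
# ----------------------------------------------------------------------

def _final_counts(params: TelegraphParams, n_cells: int, t_end: float,
                  rng: np.random.Generator) -> np.ndarray:
    """mRNA counts of ``n_cells`` independent cells at ``t_end``, via an
    exact SSA advanced for all cells in lock-step (cells that pass t_end
    freeze at their pre-crossing state)."""
    n = params.n_copies
    on = np.zeros((n_cells, n), dtype=bool)
    m = np.zeros(n_cells, dtype=np.int64)
    t = np.zeros(n_cells)
    idx = np.arange(n_cells)
    out = np.zeros(n_cells, dtype=np.int64)
    while idx.size:
        copy_rates = np.where(on, params.k_off, params.k_on)
        switch_sum = copy_rates.sum(axis=1)
        prod = params.s_a * on.sum(axis=1)
        total = switch_sum + prod + params.delta_m * m
        t = t + rng.exponential(1.0, idx.size) / total
        done = t > t_end
        if done.any():
            out[idx[done]] = m[done]
            keep = ~done
            idx, on, m, t = idx[keep], on[keep], m[keep], t[keep]
            copy_rates, switch_sum, prod = copy_rates[keep], switch_sum[keep], prod[keep]
            total = total[keep]
            if idx.size == 0:
                break
        u = rng.random(idx.size) * total
        c0 = copy_rates[:, 0]
        flip0 = u < c0
        on[flip0, 0] = ~on[flip0, 0]
        if n == 2:
            flip1 = ~flip0 & (u < switch_sum)
            on[flip1, 1] = ~on[flip1, 1]
        produce = ~(u < switch_sum) & (u < switch_sum + prod)
        degrade = ~(u < switch_sum + prod)
        m[produce] += 1
        m[degrade] -= 1
    return out


def population_mean(params: TelegraphParams, n_cells: int,
                    t_obs: float | None = None, seed=None) -> float:
    """Average mRNA count over ``n_cells`` independent cells at one
    observation time (default: after a burn-in of five mRNA lifetimes)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    t_obs = default_t_obs(params) if t_obs is None else t_obs
    rng = np.random.default_rng(seed)
    return float(_final_counts(params, n_cells, t_obs, rng).mean())


def population_moments(params: TelegraphParams, n_cells: int,
                       t_obs: float | None = None, seed=None,
                       n_batches: int = 20) -> dict[str, float]:
    """Empirical mean and Fano factor with batch-based standard errors."""
    if n_cells < n_batches:
        raise ValueError("need at least one cell per batch")
    t_obs = default_t_obs(params) if t_obs is None else t_obs
    rng = np.random.default_rng(seed)
    counts = _final_counts(params, n_cells, t_obs, rng)
    mean = counts.mean()
    fano = counts.var() / mean
    batches = np.array_split(counts, n_batches)
    b_mean = np.array([b.mean() for b in batches])
    b_fano = np.array([b.var() / b.mean() for b in batches])
    return {
        "mean": float(mean),
        "mean_se": float(b_mean.std(ddof=1) / math.sqrt(n_batches)),
        "fano": float(fano),
        "fano_se": float(b_fano.std(ddof=1) / math.sqrt(n_batches)),
        "n_cells": int(n_cells),
    }


def population_delta(params: TelegraphParams, n_cells: int,
                     t_obs: float | None = None, seed=None) -> float:
    """delta of two independent population means — the in-silico analogue
    of a two-replicate measurement on populations of ``n_cells`` cells."""
    t_obs = default_t_obs(params) if t_obs is None else t_obs
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(4)
    for attempt in range(2):
        c1, c2 = children[2 * attempt: 2 * attempt + 2]
        m1 = population_mean(params, n_cells, t_obs, seed=c1)
        m2 = population_mean(params, n_cells, t_obs, seed=c2)
        if m1 + m2 > 0:
            return _delta(m1, m2)
    raise ValueError("both population means were zero twice; delta undefined")


@dataclass
class PopulationDeltaCurve:
    """Mean and spread of population delta as a function of population size.

    ``n_valid`` counts the repeats whose delta was defined; tiny populations
    of a weakly expressed gene can yield two zero means, for which delta is
    undefined (the in-vivo analogue is a gene failing the expression
    cutoff)."""

    sizes: tuple[int, ...]
    mean_delta: np.ndarray
    sd_delta: np.ndarray
    repeats: int
    seed: int
    params: TelegraphParams
    n_valid: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "size": self.sizes,
            "mean_delta": self.mean_delta,
            "sd_delta": self.sd_delta,
            "repeats": self.repeats,
            "n_valid": self.n_valid if self.n_valid is not None else self.repeats,
            "seed": self.seed,
        })


def delta_vs_popsize(params: TelegraphParams, sizes: Sequence[int],
                     repeats: int, seed: int,
                     t_obs: float | None = None) -> PopulationDeltaCurve:
    """Mean and sd of population delta for increasing population sizes.

    Counter-based seeding: every (size, repeat) draws its own child seed
    from the master SeedSequence, so the curve is reproducible and the
    repeats are independent.
    """
    sizes = tuple(int(s) for s in sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sizes) * repeats)
    means, sds, n_valid = [], [], []
    for i, size in enumerate(sizes):
        vals = []
        for r in range(repeats):
            try:
                vals.append(population_delta(params, size, t_obs,
                                             seed=children[i * repeats + r]))
            except ValueError:
                continue  # both population means zero: delta undefined
        if len(vals) < 2:
            raise ValueError(f"fewer than 2 defined delta values at size {size}")
        means.append(np.mean(vals))
        sds.append(np.std(vals, ddof=1))
        n_valid.append(len(vals))
    return PopulationDeltaCurve(
        sizes=sizes, mean_delta=np.asarray(means), sd_delta=np.asarray(sds),
        repeats=repeats, seed=seed, params=params, n_valid=np.asarray(n_valid),
    )


def fit_popsize_scaling(curve: PopulationDeltaCurve) -> float:
    """Slope of log10(mean delta) vs log10(size); -1/2 under CLT averaging."""
    x = np.log10(np.asarray(curve.sizes, dtype=float))
    y = np.log10(curve.mean_delta)
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
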