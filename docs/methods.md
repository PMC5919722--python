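# Methods

## The problem

Deleting one copy of a chromosomal segment leaves every gene inside it with
a single dose. Beyond lowering mean expression, reduced dose can make
expression *less reproducible* between genetically identical animals. This
package measures that organism-level variability in deficiency (Df) line
RNA-seq panels, relates it to the magnitude of each gene's regulatory
response to dose loss, asks whether chromatin occupancy (the H4K16
acetyltransferase MOF, acting in the male-X MSL complex and the autosomal
NSL complex) dampens it, and uses an exact stochastic simulation to show
that gene-intrinsic (single-cell) transcriptional noise cannot be its
source.

## The delta statistic

With two biological replicates per (gene, line, sex) measurement,

    delta = 2 |FPKM1 - FPKM2| / (FPKM1 + FPKM2),

the absolute replicate difference over the replicate mean. Properties:
symmetric, scale-free, bounded in [0, 2), and for a pair exactly equal to
twice the coefficient of variation under the population (divisor-n)
convention — `cv` defaults to that convention so the identity is exact at
machine precision. With triplicates, `delta_multi` averages the three
pairwise values. Two replicates cannot estimate a single gene's noise;
delta is only ever used as a *pooled* statistic, comparing thousands of
(gene, line) measurements between groups with two-sided Wilcoxon rank-sum
tests (exact enumeration for untied samples up to n = 50, tie-corrected
normal approximation otherwise, via `scipy.stats.mannwhitneyu`; an
independent label-permutation oracle backs this in the test suite).

Genes count as expressed only when every replicate of the comparison group
reaches the FPKM cutoff. The cutoff is the 95th percentile (linear
interpolation) of intergenic background signal; because "the 95th
percentile" and "the median of the top-5% tail" are both defensible
readings of a percentile-of-tail rule, both are implemented
(`derive_cutoff(method=...)`), and a fixed cutoff (e.g. the 0.6829118 FPKM
value appropriate to the published DrosDel whole-fly tables) is available
via `method="fixed"`. The cutoff guarantees both replicates are positive,
so delta < 2 strictly.

## Dose assignment

Intervals follow BED conventions (0-based, half-open) throughout. A gene is
one-dose in a line iff its span is contained in the line's deletion on the
same arm; non-overlapping genes are two-dose; genes straddling a breakpoint
are excluded from both groups in that line, since a truncated allele's
expression is not interpretable as either dose. Lines without a recorded
deletion are two-dose throughout.

Besides pooled rank-sum comparisons, the one-dose pool is tested against a
resampled null of "the same genes where two-dose": each draw re-assigns
every one-dose (gene, line) measurement to a uniformly random line in which
that gene is two-dose and pools the medians; the empirical p uses the
add-one rule (1 + #{null >= observed}) / (B + 1). How the original
histogram of null medians was constructed is not fully determined — per
gene or per line — so a per-line variant (one null median per line) is
implemented behind `scheme="line"`; the gene-wise scheme is the default.

## Dosage response

With no regulatory response, halving dose halves expression: fold change
FC = 0.5 against the pooled two-dose reference (all same-sex, same-tissue
replicates of lines where the gene is two-dose and expressed; no single
control line is singled out). The dosage response is the deviation from
that baseline in absolute log2 units:

    response_raw = | log2(FC) + 1 |,
    response_bin = | round_half_even(log2(FC)) + 1 |.

So FC = 0.5 scores 0; FC = 1 (full compensation) and FC = 0.25 (matching
anticompensation) both score 1; the score is invariant under the reflection
FC -> 1/(4 FC). A circulating alternative form, |log2(FC + 1)| with FC
rounded to the nearest integer, violates the halving-baseline convention
(it scores FC = 1 as 1 but FC = 0.5 as 0 only after rounding FC itself to
0); it is kept behind `response_score(..., literal=True)` for comparison
only. Rounding is half-to-even; exact .5 ties in log2 space have measure
zero in practice.

Bins 0, 1 and >= 2 (pooled) are compared by adjacent rank-sum tests in the
reported output. For the single question "does delta increase with the
bin?" — an ordered alternative over three levels — the pipeline's recovery
check uses a Spearman rank trend of delta against the bin level, with the
additional requirement that the bin medians are strictly increasing;
max-of-adjacent-p would be a conservative multi-test proxy for the same
ordering.

## Line-to-line CV and occupancy strata

Across a panel sharing one genetic background, lines where a gene is
two-dose act as replicates. Per gene, sex and tissue, the CV is taken over
per-line replicate means, restricted to lines where the gene passes the
cutoff in all replicates, requiring >= 3 usable lines; genes on the
Df-bearing arm (default 2L) and spike-ins are excluded. Whether the
original computation averaged replicates first is unknown, so an
all-samples variant is available (`per_line_mean=False`); averaging first
is the default as it removes within-line technical spread from a
between-line statistic. Occupancy is binarised as any >= 1 bp overlap
between the gene span and a called peak (peak calling itself is out of
scope; peaks are inputs). Housekeeping status is tau strictly below the 5th
percentile of observed tau scores; missing tau/EBox/NSL annotations exclude
a gene from that stratification only. Strata (X vs autosomes,
housekeeping, EBox, NSL activation) are compared flagged-vs-unflagged
within each stratum, per sex — the two sexes' CVs of one gene share line
effects and are therefore never pooled into a single rank-sum.

## Telegraph-model simulation

Each gene copy is a two-state promoter: OFF -> ON at k_on, ON -> OFF at
k_off, transcription at s_a while ON, first-order mRNA decay at delta_m;
two copies are independent reaction channels inside one exact Gillespie
simulation (statistically identical to two separate runs, cheaper). All
simulations start with every copy OFF and zero mRNA. Closed forms used as
oracles:

    E[m]  = n_copies * k_on/(k_on + k_off) * s_a/delta_m
    Fano  = 1 + s_a k_off / ((k_on + k_off)(k_on + k_off + delta_m))

(the Fano factor is copy-number independent, and -> 1 as k_off -> 0, the
constitutive/Poisson limit).

Default regime: k_on = k_off = 0.02/s (35 s switching half-time),
s_a = 0.01/s (0.02/s for the compensated single copy), delta_m = 0.008/s.
The decay rate 0.008/s implies an ~87 s mRNA half-life, not the 14 minutes
sometimes quoted next to it; the rate is treated as authoritative and a
`DELTA_M_14MIN` preset (ln 2 / 840 s) exposes the alternative.

A "measurement" is the mean mRNA count over N independent cells at a single
observation time after a burn-in of five mRNA lifetimes (5/delta_m =
625 s, by which the initial all-OFF transient has decayed to < 1%);
population delta is the delta of two such independent means. The
observation protocol is a design choice — per-time-point averages could
also be time-averaged, and a trajectory-recording `simulate_cell` supports
that — but the single-time protocol mirrors a two-replicate RNA-seq
measurement most directly. By the CLT, mean delta scales as N^(-1/2); the
fitted log-log slope over N = 10..10^4 sits in [-0.55, -0.45]. At N = 1 the
delta of a weakly expressed gene is occasionally undefined (two zero
means); such repeats are dropped and counted in `n_valid`, the analogue of
a gene failing the expression cutoff. Every (size, repeat) draws a child
seed from one master `SeedSequence`, so curves are reproducible and
parallelisable.

The practical conclusion the simulation supports: at the cell counts of a
whole organism (>> 10^4), gene-intrinsic noise contributes delta values far
below even spike-in technical noise, so organism-level variability
differences between dose groups must come from gene-extrinsic, organism-
coordinated sources.

## Synthetic cohort generator

The generator produces cohorts with the statistical structure the analysis
assumes, plus the planted truth, so every stage is testable without
external data. On the log2 scale:

    log2 FPKM[g, line, rep] = log2 B_g + dose_term + eps_line + eps_rep

with log2 B_g ~ N(3, 2) (median FPKM ~ 8 with a wide dynamic range);
dose_term = -1 + rho_g for one-dose measurements, rho_g ~ N(0, sigma_rho)
the signed dosage response (so the pipeline-visible response magnitude is
|rho_g|); eps_line ~ N(0, 0.35 * kappa) shared by a line's sexes and
replicates; eps_rep ~ N(0, 0.25 * kappa) per sample. The noise multiplier
kappa carries the planted effects:

| effect                   | kappa factor            | applies to            | default |
|--------------------------|-------------------------|-----------------------|---------|
| one-dose inflation       | 1 + a0 + a1·\|rho_g\|   | line + replicate      | a0=0.5, a1=1.0 |
| occupancy dampening      | m                       | line + replicate      | m=0.6   |
| female noise excess      | female_noise            | replicate             | 1.3     |
| male-X compensation      | male_x_noise (<= 1), dose term 0 | replicate    | 0.8     |

Noise effects that delta must detect necessarily live on the replicate
component (delta is blind to line effects, which cancel between a line's
replicates), while the CV analysis — taken across two-dose lines — sees
the line component; the occupancy and inflation factors therefore act on
both components. Dosage responses shift means only.

Structure defaults are the study conditions: 99 Df lines on 2L deleting 40
contiguous genes each (breakpoints placed in intergenic gaps, so no
partial-overlap exclusions arise by construction), 2 replicates x 2 sexes
(the head preset: 30 X-arm lines, 3 replicates, females), ~11,800 genes
with arm proportions like the fly genome, 92 spike-ins with 0.05 log2
technical sd, and 3,000 intergenic log-normal signals (log2 mean -3, sd
1.5) whose analytic 95th percentile, ~0.69 FPKM, matches the scale of the
published cutoff. sigma_rho = 1.0 populates response bins 0/1/>=2 in
proportions like the observed panels. Occupancy peaks are placed inside
flagged gene spans (fraction 0.25); tau is uniform on [0, 1]; EBox and NSL
flags are independent Bernoulli draws. `CohortConfig.null()` zeroes every
kappa effect while keeping the expression effects of dose.

What the generator does *not* emulate: count-based sampling noise and its
mean-variance dependence (all dispersions are log-normal and
expression-independent), correlated responses of co-regulated genes,
linked-gene effects near breakpoints, batch structure, or any relation
between occupancy and expression level. Passing recovery tests therefore
shows the pipeline detects effects of the planted form at realistic sizes
— not that real data contain them.

## Calibration and recovery

On default cohorts the pipeline must recover all four planted orderings
(one-dose > two-dose delta; delta increasing with response bin; flagged CV
< unflagged in both sexes; female > male delta) at p < 0.01 in >= 95% of
seeds, and under the null configuration each test's rejection rate at
alpha = 0.05 must stay inside the 99% binomial band. The shipped suite
runs 20 seeds per arm; the calibration design is 200 seeds and can be run
by looping `workflows.recovery_pvalues` with more seeds.

Problem sizes used by the shipped suite and drivers: cohorts of ~11,900
rows x 396 samples (20 recovery + 20 null seeds), SSA populations up to
2 x 10^4 cells for moment checks and 10^1..10^4 cells x 40 repeats for the
scaling fit; the analysis drivers use one seed (7) and sizes 1..10^3 at 30
repeats for the quick-look curve.

## Known limitations

* delta's add-one empirical p cannot fall below 1/(B+1); B = 999 bounds it
  at 0.001.
* The asymptotic rank-sum path is used for all pools above n = 50; for the
  million-measurement pools this is the only practical choice, and the
  permutation oracle validates it only at small n.
* The SSA observation-time protocol reports one time point; genes with
  mRNA lifetimes much longer than the burn-in multiple would need a larger
  `multiple` in `default_t_obs`.
* Fold-change references pool all two-dose lines; with few lines (< ~5)
  the reference itself is noisy and response bins become unstable.
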