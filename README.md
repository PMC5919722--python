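# dosevar

Organism-level gene expression variability as a function of gene dose, for
*Drosophila* deficiency (Df) line RNA-seq panels — and for anyone studying
how copy-number loss changes not just the level but the *reproducibility*
of gene expression.

Flies heterozygous for an engineered multi-gene deletion carry one dose of
every deleted gene. With two biological replicates per line and sex, the
replicate-to-replicate variability of a measurement is

    delta = 2 |FPKM1 - FPKM2| / (FPKM1 + FPKM2),

a scale-free statistic in [0, 2) that equals exactly **2 x CV** (population
convention) for a pair. Single genes cannot be scored with two replicates,
but pooling delta over thousands of (gene, line) measurements supports
rank-sum comparisons between groups: one-dose vs two-dose genes, females vs
males, genes binned by dosage response |log2(FC) + 1| (0 = pure halving,
1 = full compensation or matching anticompensation), and — via the
line-to-line CV across the ~99 lines where a gene is two-dose — genes
with vs without MOF/NSL chromatin occupancy. An exact Gillespie simulation
of the two-state (telegraph) promoter model shows that gene-intrinsic
bursting noise averages out as N^(-1/2) across a cell population and is
invisible at organism scale, so dose-linked variability differences must be
gene-extrinsic.

A synthetic cohort generator with planted ground truth (halved one-dose
expression, response-coupled noise inflation, occupancy noise dampening,
female noise excess, low-noise spike-ins, intergenic background) stands in
for the deposited panels, so the full pipeline is testable offline.

## Worked example

```python
import dosevar as dv
from dosevar import workflows as wf

# delta and the exact CV identity
dv.delta(8, 4)            # 0.6666666666666666
2 * dv.cv([8, 4])         # 0.6666666666666666

# telegraph model: one uncompensated copy vs two copies
dv.stationary_mean(dv.ONE_DOSE)   # 0.625
dv.stationary_mean(dv.TWO_DOSE)   # 1.25
dv.fano_factor(dv.ONE_DOSE)       # 1.1041666666666667

# a full synthetic cohort analysis (99 lines x 40 genes, both sexes)
ca = wf.prepare(dv.CohortConfig(), seed=7)
pools, cmp = wf.dose_comparison(ca)
print(cmp.median_a, cmp.median_b, cmp.p_value)
```

The last call prints `0.34307... 0.15968... 0.0`: pooled one-dose
measurements have roughly twice the median delta of two-dose measurements,
and with ~6,500 one-dose against ~2.2 million two-dose values the rank-sum
p-value underflows to zero. The numbered drivers under `analysis/` run each
stage with narrative output and write tables under `results/`:

```bash
python analysis/01_generate_cohort.py    # cohort structure + cutoff (~0.69 FPKM)
python analysis/02_dose_variability.py   # one- vs two-dose delta, spike-ins, median-null
python analysis/03_dosage_response.py    # delta across response bins 0 / 1 / >=2
python analysis/04_telegraph_noise.py    # population-averaged intrinsic noise curves
python analysis/05_occupancy_strata.py   # occupancy-stratified CV comparisons
```

For example, `02_dose_variability.py` reports (seed 7):

```
F one-dose (n=3213, median 0.3853) vs F two-dose (n=1105827, median 0.1863): p = 0
F two-dose (n=1105827, median 0.1863) vs F spike-in (n=9108, median 0.0330): p = 0
median-null [F]: observed 0.3850 vs null max 0.2019 over B=999 draws -> empirical p = 0.001
```

i.e. one-dose genes are noisier than the same cohort's two-dose genes, all
biological variability sits far above the spike-in technical floor, and the
observed one-dose median exceeds every resampled two-dose median of the
same genes. `04_telegraph_noise.py` shows mean delta falling from ~1.5 at
N = 1 cell to ~0.04 at N = 1000 — the N^(-1/2) averaging that rules out
intrinsic noise at organism scale.

A `dosevar` console script exposes the same stages on files
(`dosevar generate | dose | delta | compare | response | simulate |
occupancy`); every output TSV carries a `#`-commented header and a JSON
manifest with the seed and parameters.

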