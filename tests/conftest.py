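import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dosevar.synth import CohortConfig
from dosevar import workflows as wf

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: Down-scaled cohort for unit tests: same structure (one Df arm, contiguous
#: 15-gene deletions, both sexes, spike-ins, intergenic background) at a
#: fraction of the study size.
SMALL_CONFIG = CohortConfig(
    arms={"2L": 150, "2R": 80, "3L": 80, "3R": 80, "X": 60, "4": 10},
    n_df_lines=12,
    genes_per_df=15,
    spike_in_count=20,
    n_intergenic=500,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_analysis():
    """A prepared small cohort: matrix + dose table + cutoff (seed 11)."""
    return wf.prepare(SMALL_CONFIG, seed=11)


@pytest.fixture()
def toy_matrix():
    """Hand-built 4-gene x 6-sample matrix: 3 lines x 2 replicates, female.

    Gene layout on 2L (one gene per 3 kb slot): g1 [0,2000), g2 [3000,5000),
    g3 [6000,8000); gx is an X gene at [0,2000). Values chosen for hand
    arithmetic in dose/response tests.
    """
    from dosevar.expression_io import ExpressionMatrix

    genes = pd.DataFrame({
        "gene_id": ["g1", "g2", "g3", "gx"],
        "arm": ["2L", "2L", "2L", "X"],
        "start": [0, 3000, 6000, 0],
        "end": [2000, 5000, 8000, 2000],
        "tau": [0.1, 0.5, 0.9, 0.3],
        "ebox": [True, False, True, False],
        "nsl_activated": [True, True, False, False],
        "is_spike_in": [False] * 4,
    })
    samples = pd.DataFrame({
        "sample_id": ["L1_F_r1", "L1_F_r2", "L2_F_r1", "L2_F_r2", "L3_F_r1", "L3_F_r2"],
        "line_id": ["L1", "L1", "L2", "L2", "L3", "L3"],
        "sex": ["F"] * 6,
        "sex_transformed": [False] * 6,
        "tissue": ["whole"] * 6,
        "replicate": [1, 2, 1, 2, 1, 2],
    })
    fpkm = np.array([
        [5.0, 5.0, 9.0, 11.0, 10.0, 10.0],   # g1: one-dose in L1, fc = 0.5
        [4.0, 8.0, 6.0, 6.0, 6.0, 6.0],      # g2: delta = 2/3 in L1
        [0.4, 2.0, 3.0, 3.0, 3.0, 3.0],      # g3: fails cutoff in L1 rep1
        [7.0, 7.0, 7.0, 7.0, 7.0, 7.0],      # gx: constant
    ])
    return ExpressionMatrix(genes, samples, fpkm)
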