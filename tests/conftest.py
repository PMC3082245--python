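import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import nestvar as nv

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_study(values, n_mice=None, reps=2, cages_of_two=True, controls=0):
    """Build a small balanced ExpressionStudy from a 2-D array.

    Columns are grouped mouse-by-mouse with ``reps`` replicates each.  The
    last ``controls`` rows are flagged as negative controls.
    """
    values = np.asarray(values, dtype=float)
    n_probes, n_samp = values.shape
    if n_mice is None:
        n_mice = n_samp // reps
    assert n_mice * reps == n_samp
    sample_ids = [f"m{i + 1:02d}_r{r + 1}" for i in range(n_mice) for r in range(reps)]
    mice = [f"m{i + 1:02d}" for i in range(n_mice) for _ in range(reps)]
    if cages_of_two and n_mice % 2 == 0:
        cages = [f"c{i // 2 + 1}" for i in range(n_mice) for _ in range(reps)]
    else:
        cages = [f"c{i + 1}" for i in range(n_mice) for _ in range(reps)]
    samples = pd.DataFrame(
        {
            "mouse": mice,
            "cage": cages,
            "replicate": [r + 1 for _ in range(n_mice) for r in range(reps)],
            "batch": ["B1"] * n_samp,
            "tissue": ["liver"] * n_samp,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    probe_ids = [f"g{i + 1:04d}" for i in range(n_probes)]
    probes = pd.DataFrame(
        {
            "gene_symbol": [f"G{i + 1:04d}" for i in range(n_probes)],
            "is_negative_control": [0] * (n_probes - controls) + [1] * controls,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    vals = pd.DataFrame(values, index=probes.index, columns=samples.index)
    return nv.ExpressionStudy(vals, samples, probes)


@pytest.fixture
def tiny_study():
    """3 mice x 2 replicates, 2 genes; the hand-computable ANOVA example."""
    return make_study([[1, 3, 5, 7, 2, 4], [0, 10, 5, 5, 4, 6]])


@pytest.fixture
def null_study():
    """Pure within-mouse noise: 400 genes, 12 mice x 2 replicates."""
    cfg = nv.SimulationConfig(
        n_genes=400, n_negative_controls=0, sigma2_cage=0.0, sigma2_mouse=0.0,
        sigma2_within=1.0, frac_expressed=1.0, batch_effect_sd=0.0, seed=101,
    )
    return nv.simulate_study(cfg).study
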