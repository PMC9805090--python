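import warnings

import numpy as np
import pandas as pd
import pytest

from msewas import synthetic

# statsmodels emits benign convergence chatter on probes near separation;
# the code under test handles those cases explicitly
warnings.filterwarnings("ignore", message="Maximum Likelihood optimization")


@pytest.fixture(scope="session")
def small_cohort():
    """A 100-sample, 2000-probe cohort with strong planted effects,
    shared across tests that only read from it."""
    cfg = synthetic.SimulationConfig(
        n_samples=100,
        n_probes=2000,
        n_truth_dmps=30,
        effect_sizes=(0.05, 0.10),
        n_clock_cpgs=12,
        n_mqtl_pairs=5,
        n_null_snvs=10,
        seed=1,
    )
    return synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted effects of any kind."""
    cfg = synthetic.SimulationConfig(
        n_samples=200,
        n_probes=2000,
        n_truth_dmps=0,
        n_truth_dmrs=0,
        n_mqtl_pairs=0,
        n_null_snvs=6,
        n_clock_cpgs=5,
        seed=7,
    )
    return synthetic.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_annotation(probes, chromosome="1", **overrides):
    """Minimal clean annotation for ad-hoc matrices."""
    n = len(probes)
    base = {
        "probe_id": list(probes),
        "chromosome": [chromosome] * n,
        "position": list(range(1000, 1000 + 2000 * n, 2000)),
        "gene": [""] * n,
        "feature": ["IGR"] * n,
        "cgi_context": ["opensea"] * n,
        "non_cpg": [False] * n,
        "snp_related": [False] * n,
        "multi_hit": [False] * n,
        "autosomal": [True] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)
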