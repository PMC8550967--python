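import logging

import numpy as np
import pytest

from methbiotype.pipeline import PipelineConfig, run_discovery
from methbiotype.synthetic import SyntheticConfig, generate_cohort

logging.getLogger("methbiotype").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, fully structured cohort for unit-level checks."""
    cfg = SyntheticConfig(
        n_control=30, n_g1=15, n_g2=15, n_genes=220,
        n_signal_genes_g1=10, n_signal_genes_g2=10,
        n_phys_factor_genes=12, n_intergenic_probes=20, seed=5,
    )
    return (cfg, *generate_cohort(cfg))


@pytest.fixture(scope="session")
def discovery_cohort():
    """The reference study-scale cohort (seed 7) used by the end-to-end
    recovery, transfer and washout checks."""
    cfg = SyntheticConfig(seed=7)
    return (cfg, *generate_cohort(cfg))


@pytest.fixture(scope="session")
def discovery_fit(discovery_cohort):
    cfg, beta, annot, clinical, truth = discovery_cohort
    pcfg = PipelineConfig(n_iter=500, top_k=100, seed=7)
    result = run_discovery(beta, annot, clinical, pcfg)
    return pcfg, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
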