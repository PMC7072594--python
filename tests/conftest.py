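import numpy as np
import pytest

from stratsurv.simulate import SimulationConfig, simulate_study
from stratsurv.survival import SurvivalRecord


@pytest.fixture
def four_subject_groups():
    """Events at t=1,2 in group 1 and t=3,4 in group 2, no censoring."""
    g1 = [SurvivalRecord("a", 1.0, 1), SurvivalRecord("b", 2.0, 1)]
    g2 = [SurvivalRecord("c", 3.0, 1), SurvivalRecord("d", 4.0, 1)]
    return g1, g2


@pytest.fixture
def three_subject_records():
    """Event at 1, censored at 2, event at 3."""
    return [
        SurvivalRecord("a", 1.0, 1),
        SurvivalRecord("b", 2.0, 0),
        SurvivalRecord("c", 3.0, 1),
    ]


@pytest.fixture
def small_study():
    cfg = SimulationConfig(
        n_samples=80,
        n_genes=60,
        hazard_ratio_hi_vs_lo=2.5,
        true_cutpoint_quantile=0.6,
        n_de_genes_up=5,
        n_de_genes_down=5,
        seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
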