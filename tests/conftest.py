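import numpy as np
import pandas as pd
import pytest

from lpasig import (SimulationConfig, paper_design,
                    simulate_attribution_dataset)
from lpasig.containers import ExpressionExperiment


@pytest.fixture(scope="session")
def design():
    """Three-line / four-receptor design: PC3 {1,2,3,6}, MDA-MB-231 {1,2},
    MCF-7 {2,6}."""
    return paper_design()


@pytest.fixture(scope="session")
def noiseless_dataset(design):
    cfg = SimulationConfig(design=design, n_genes=200,
                           n_planted_per_receptor=20, effect_size=2.0,
                           noise_cv=0.0, n_duplicate_probesets=2, seed=7)
    return simulate_attribution_dataset(cfg)


@pytest.fixture
def tiny_experiment():
    """Two probe sets, two lines, two replicates per condition, hand values."""
    cols = pd.MultiIndex.from_tuples(
        [("A", "control", "1"), ("A", "control", "2"),
         ("A", "treated", "1"), ("A", "treated", "2"),
         ("B", "control", "1"), ("B", "control", "2"),
         ("B", "treated", "1"), ("B", "treated", "2")],
        names=["cell_line", "condition", "replicate"])
    values = pd.DataFrame(
        [[100.0, 200.0, 300.0, 300.0, 80.0, 80.0, 80.0, 80.0],
         [50.0, 50.0, 40.0, 30.0, 10.0, 10.0, 26.0, 26.0]],
        index=pd.Index(["ps1", "ps2"], name="probe_set"), columns=cols)
    return ExpressionExperiment(values)


def make_calls_frame(patterns: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Build a calls DataFrame from {probe: {line: call}}."""
    return pd.DataFrame(patterns).T


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
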