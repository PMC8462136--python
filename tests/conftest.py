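import numpy as np
import pytest

from milfoilsdm import SimulationConfig, generate_landscape
from milfoilsdm.models import RFHyper
from milfoilsdm.pipeline import ExperimentConfig


@pytest.fixture(scope="session")
def default_landscape():
    """One landscape at the survey-design defaults (184/284/801)."""
    return generate_landscape(SimulationConfig(seed=1))


@pytest.fixture()
def tiny_sim():
    """Small, fast landscape config for structural/pipeline tests."""
    return SimulationConfig(
        n_presence=40, n_absence=60, n_unsurveyed=200,
        effect_weight=5.0, latent_weight=0.0, seed=3,
    )


@pytest.fixture()
def tiny_experiment(tiny_sim, tmp_path):
    return ExperimentConfig(
        simulation=tiny_sim,
        cv_iterations=2,
        k_folds=3,
        block_side_occurrence=60.0,
        block_side_proximal=40.0,
        hyper=RFHyper(n_trees=50),
        importance_repeats=2,
        seed=3,
        out_dir=str(tmp_path / "run"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
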