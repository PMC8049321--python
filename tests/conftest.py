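import warnings

import numpy as np
import pandas as pd
import pytest

from whaletrends import synthetic
from whaletrends.cli import STAGE_ORDER, run_stage


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def humpback_only_config():
    profiles = {"humpback": synthetic.default_species_profiles()["humpback"]}
    return synthetic.SimulationConfig(seed=0, species_profiles=profiles)


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """One full default pipeline run shared by integration-level tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for stage in STAGE_ORDER:
            if stage == "forecast":
                continue
            run_stage(stage, outdir, seed=11)
    return outdir


@pytest.fixture(scope="session")
def pipeline_timing(pipeline_dir):
    return pd.read_csv(pipeline_dir / "timing.csv")


def rng_for(case: str, seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(abs(hash((case, seed))) % 2**31)
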