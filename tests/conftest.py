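import numpy as np
import pandas as pd
import pytest

from probpanel.pipeline import PipelineConfig, run_pipeline
from probpanel.register_synthesis import FrameConfig, default_truth


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default-scale pipeline run (~28,000 invited), shared by all
    tests that inspect end-to-end behaviour."""
    return run_pipeline(PipelineConfig(), seed=1)


@pytest.fixture(scope="session")
def tiny_config():
    """A deliberately small configuration for fast smoke tests."""
    frame = FrameConfig(
        n_municipalities=12,
        total_pop_16plus=12_000,
        state_shares={"Berlin": 0.5, "Bavaria": 0.5},
    )
    return PipelineConfig(
        frame=frame, total_psus=2, min_psus_per_state=1,
        oversample_factors={}, run_models=False,
    )


def make_ledger(rows):
    """Small helper: disposition-ledger persons frame from dict rows."""
    defaults = {
        "person_id": None, "final_code": "noncontact", "consented": False,
        "confirmed": False, "validated": False, "responded": False,
        "sex": "male", "design_weight": 1.0,
    }
    out = []
    for i, r in enumerate(rows):
        row = dict(defaults)
        row["person_id"] = f"x{i}"
        row.update(r)
        out.append(row)
    return pd.DataFrame(out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
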