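import pandas as pd
import pytest

from stressmodes.pattern_classifier import MODES
from stressmodes.synthetic_data import SimulationSpec, simulate_dataset
from stressmodes.tables_io import ContrastTable


@pytest.fixture
def transcript_table():
    """Small ST transcript table covering retain/exclude gate cases."""
    df = pd.DataFrame(
        {
            "log2fc": [2.0, 0.5, -3.0, -1.5],
            "fdr": [0.01, 0.001, 0.2, 0.04],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="feature_id"),
    )
    return ContrastTable("ST", "transcript", df)


@pytest.fixture
def metabolite_table():
    """Small metabolite table covering the VIP and FC gates."""
    df = pd.DataFrame(
        {
            "log2fc": [1.32, 0.58, -1.32, -2.0],
            "vip": [1.3, 2.0, 0.9, 1.5],
            "fdr": [0.01, 0.01, 0.01, 0.01],
        },
        index=pd.Index(["m1", "m2", "m3", "m4"], name="feature_id"),
    )
    return ContrastTable("SWL", "metabolite", df)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noiseless simulated dataset: 5 features per mode incl. non_assigned."""
    spec = SimulationSpec(
        n_per_mode={m: 5 for m in (*MODES, "non_assigned")},
        n_unique={"ST": 6, "WL": 8, "SWL": 15},
        n_null=20,
        seed=42,
    )
    return simulate_dataset(spec)
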