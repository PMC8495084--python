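import sys
from pathlib import Path

import numpy as np
import pytest

from dta_meta.studies import StudyRecord

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_panel(rng, k=6, label="test", low=1, high=200):
    """Random panel of studies with strictly positive cells."""
    cells = rng.integers(low, high, size=(k, 4))
    return [
        StudyRecord(
            study_id=f"s{i}",
            test_label=label,
            tp=int(c[0]),
            fp=int(c[1]),
            fn=int(c[2]),
            tn=int(c[3]),
        )
        for i, c in enumerate(cells)
    ]


@pytest.fixture
def panel(rng):
    return make_panel(rng, k=8)


@pytest.fixture
def two_arm_csv(tmp_path):
    """A small paired two-arm dataset written to CSV."""
    from dta_meta.simulate import SynthConfig, generate_paired_panel
    from dta_meta.studies import write_studies

    records = generate_paired_panel(
        SynthConfig(k=8, test_label="ICE", seed=1),
        SynthConfig(k=8, test_label="TEE", seed=2),
        shared_seed=99,
    )
    path = tmp_path / "two_arm.csv"
    write_studies(records, path)
    return path
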