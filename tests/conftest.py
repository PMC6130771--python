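import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import devotei as d

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def worked_example():
    return d.generate_worked_example()


@pytest.fixture(scope="session")
def worked_example_expected():
    return json.loads((DATA_DIR / "worked_example_expected.json").read_text())


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.lognormal(2.0, 1.0, size=(20, 5)),
        index=[f"g{i:02d}" for i in range(20)],
        columns=[f"s{j}" for j in range(5)],
    )
    return d.ExpressionMatrix(data=data, scale="normalized_linear")


@pytest.fixture()
def simple_timeline():
    return d.StageTimeline(
        stage_ids=["s0", "s1", "s2", "s3", "s4"],
        periods=["preMZT", "early", "early", "middle", "late"],
    )
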