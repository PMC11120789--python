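import numpy as np
import pandas as pd
import pytest

from md3f import FeatureTable, StudyDesign


@pytest.fixture
def small_table() -> FeatureTable:
    rng = np.random.default_rng(42)
    values = rng.uniform(0.5, 5.0, size=(5, 4))
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(5)],
        feature_ids=[f"otu{j}" for j in range(4)],
        values=values,
    )


@pytest.fixture
def two_group_design() -> StudyDesign:
    rows = []
    for subj, group in [("a", "ctrl"), ("b", "ctrl"), ("c", "case"), ("d", "case")]:
        for k, t in enumerate([0.0, 1.0, 2.0, 3.5, 5.0]):
            rows.append(
                {"sample": f"{subj}{k}", "subject": subj, "time": t, "group": group}
            )
    return StudyDesign(pd.DataFrame(rows))
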