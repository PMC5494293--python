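from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cqpanel import CqTable, SampleSheet


@pytest.fixture
def tiny_cq() -> CqTable:
    """4 miRNAs x 5 samples (3 healthy, 2 periodontitis) with one missing cell."""
    data = pd.DataFrame(
        {
            "H1": [30.0, 25.0, 33.0, 28.0],
            "H2": [30.5, 25.5, 33.5, 28.5],
            "H3": [29.5, 24.5, 32.5, 27.5],
            "P1": [28.0, 25.2, 35.0, np.nan],
            "P2": [28.4, 25.1, 34.6, 28.9],
        },
        index=["hsa-miR-a", "hsa-miR-b", "hsa-miR-c", "hsa-miR-d"],
    )
    return CqTable(data, panel_id="tiny")


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["H1", "H2", "H3", "P1", "P2"],
                "group": ["healthy"] * 3 + ["periodontitis"] * 2,
                "set_id": ["set1"] * 5,
                "age": [30, 40, 50, 55, 60],
                "gender": ["M", "F", "M", "F", "M"],
            }
        )
    )
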