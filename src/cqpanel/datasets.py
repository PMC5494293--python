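"""Bundled example data shipped with the package.

The example cohort is the subject table of a two-stage gingival
crevicular fluid miRNA study: a discovery set (``set1``: 5 healthy, 3
periodontitis) and a validation set (``set2``: 6 healthy, 6
periodontitis), with ages, gender, diagnosis and full-mouth clinical
parameters.  It exercises every cohort-summary code path without
external downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import MirnaList, SampleSheet

__all__ = [
    "load_example_cohort",
    "EXAMPLE_REFERENCE_MIRNAS",
    "EXAMPLE_MATCHED_PAIRS",
]

#: Reference probes used for multi-reference normalization in the
#: validation stage of the example study.
EXAMPLE_REFERENCE_MIRNAS = MirnaList(
    "reference_panel",
    (
        "hsa-miR-324-5p",
        "hsa-miR-29c-5p",
        "hsa-miR-107",
        "hsa-miR-324-3p",
        "hsa-miR-30d-5p",
    ),
)

#: Age- and gender-matched (healthy, periodontitis) subject pairs of the
#: example cohort.
EXAMPLE_MATCHED_PAIRS = (("H2", "P3"), ("H4", "P1"), ("H9", "P5"))


def load_example_cohort() -> SampleSheet:
    """Load the bundled 20-subject example cohort as a :class:`SampleSheet`."""
    with resources.files("cqpanel.data").joinpath("example_cohort.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    return SampleSheet(df)
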