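import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from aomquant import MicroscopeGeometry, paper_scenario

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def unit_geometry():
    return MicroscopeGeometry.unit()


@pytest.fixture(scope="session")
def study_truth():
    """The calibrated two-timepoint scenario (solved once per session)."""
    return paper_scenario()


def make_counts(sample_id="A", reps=2, fields=2, singles=None, aggregates=None):
    """Build a tidy count table from explicit per-(rep, field) numbers.

    ``singles[r][f]`` and ``aggregates[class][r][f]`` are counts; missing
    entries default to zero.
    """
    singles = singles or {}
    aggregates = aggregates or {}
    rows = []
    for r in range(reps):
        for f in range(fields):
            rows.append(dict(sample_id=sample_id, replicate_id=str(r + 1),
                             field_id=str(f + 1), object_type="single_cell",
                             diameter_class_um=np.nan,
                             count=singles.get((r, f), 0)))
            for c, table in aggregates.items():
                rows.append(dict(sample_id=sample_id, replicate_id=str(r + 1),
                                 field_id=str(f + 1), object_type="aggregate",
                                 diameter_class_um=float(c),
                                 count=table.get((r, f), 0)))
    return pd.DataFrame(rows)


@pytest.fixture
def make_counts_table():
    return make_counts
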