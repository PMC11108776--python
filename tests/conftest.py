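import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tmetrial.data_model import CellTable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

MARKER_COLS = ["cd8", "pd1", "tox", "foxp3", "pdl1", "pax8"]


def make_table(rows, specimen_id="S1"):
    """Build a CellTable from (x, y, compartment, markers...) tuples.

    Each row is (x, y, compartment, set-of-positive-marker-names).
    """
    recs = []
    for i, (x, y, comp, positive) in enumerate(rows):
        rec = {"cell_id": f"c{i}", "x": float(x), "y": float(y), "compartment": comp}
        for m in MARKER_COLS:
            rec[m] = m in {p.lower() for p in positive}
        recs.append(rec)
    return CellTable(specimen_id, pd.DataFrame(recs))


def random_table(rng, n=200, specimen_id="R1", compartment="tumor"):
    """Random cell table with independent marker calls (spatial tests only)."""
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x": rng.uniform(0, 500, n),
            "y": rng.uniform(0, 500, n),
            "compartment": compartment,
        }
    )
    for m in MARKER_COLS:
        df[m] = rng.random(n) < 0.3
    return CellTable(specimen_id, df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
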