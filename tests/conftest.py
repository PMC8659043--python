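import numpy as np
import pandas as pd
import pytest

from spescreen.feature_io import ConsensusFeature, FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_table(rows, run_length=34.0, scan_range=(50.0, 1000.0)):
    """Feature table from (feature_id, mz, rt, area, sample_id, replicate_id) tuples."""
    df = pd.DataFrame(
        rows, columns=["feature_id", "mz", "rt", "area", "sample_id", "replicate_id"]
    )
    return FeatureTable(df, run_length=run_length, scan_range=scan_range)


def make_consensus(specs):
    """Consensus features from (mz, rt, mean_area) triples."""
    return [
        ConsensusFeature(
            feature_id=f"f{i}", mz=mz, rt=rt, areas_per_replicate=[area], mean_area=area
        )
        for i, (mz, rt, area) in enumerate(specs)
    ]


@pytest.fixture
def triplicate_table():
    """Two samples x three replicates; one feature missing from one replicate of A."""
    rows = []
    for rep in ("r1", "r2", "r3"):
        rows.append(("f1", 200.0, 5.0, 1e5, "A", rep))
        rows.append(("f3", 400.0, 12.0, 3e5, "B", rep))
        if rep != "r2":
            rows.append(("f2", 300.0, 8.0, 2e5, "A", rep))
    return make_table(rows)
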