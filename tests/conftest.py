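import numpy as np
import pandas as pd
import pytest

from metacurate.geo_io import ExpressionMatrix, SampleRecord, SeriesRecord
from metacurate.synthetic import SimulationConfig, simulate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A 5-study, 200-gene corpus with planted effects (seed-fixed)."""
    return simulate_corpus(SimulationConfig(n_series=5, n_genes=200, seed=11))


@pytest.fixture
def breast_series():
    """A hand-written 4-sample series: 2 ductal-carcinoma cases, 2 normals."""
    texts = [
        "tissue: IDC",
        "tissue: normal breast",
        "tissue: IDC, grade 2",
        "tissue: normal breast",
    ]
    ages = ["age: 50", "age: 61", "age: 47", "age: 58"]
    samples = [
        SampleRecord(
            sample_id=f"GSM10{i}",
            series_id="GSE100",
            platform_id="GPL1",
            attributes={
                "characteristics_ch1.1": texts[i],
                "characteristics_ch1.2": ages[i],
            },
        )
        for i in range(4)
    ]
    series = SeriesRecord(
        series_id="GSE100",
        title="breast tumour study",
        series_attributes={"geo_accession": "GSE100", "title": "breast tumour study"},
        sample_ids=[s.sample_id for s in samples],
    )
    return series, samples


@pytest.fixture
def tiny_matrix():
    """4 probes x 4 samples with known values."""
    data = pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [2.0, 2.0, 2.0, 2.0],
                [0.0, 1.0, 0.0, 1.0],
                [5.0, 4.0, 3.0, 2.0],
            ]
        ),
        index=["p1", "p2", "p3", "p4"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(platform_id="GPL1", data=data)
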