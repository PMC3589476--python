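import numpy as np
import pandas as pd
import pytest

from mirscreen.io import ExpressionMatrix, SampleSheet


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 probes x 4 samples raw matrix with hand-checkable values."""
    data = pd.DataFrame(
        [
            [10.0, 20.0, 30.0, 40.0],
            [5.0, 5.0, 5.0, 5.0],
            [0.0, 1.0, 2.0, 3.0],
            [100.0, 90.0, 80.0, 70.0],
        ],
        index=["p1", "p2", "p3", "p4"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data=data, stage="raw")


@pytest.fixture
def four_cohort_sheet() -> SampleSheet:
    """Minimal sheet with 3/3/3/3 samples across the four cohorts."""
    rows = []
    i = 0
    for cohort in ("control", "bc_pre", "bc_post", "other_cancer"):
        for _ in range(3):
            i += 1
            rows.append({"sample_id": f"s{i}", "cohort": cohort})
    return SampleSheet(frame=pd.DataFrame(rows))


def random_expression(rng: np.random.Generator, n_probes: int, n_samples: int,
                      stage: str = "raw") -> ExpressionMatrix:
    data = pd.DataFrame(
        rng.uniform(0.0, 1000.0, size=(n_probes, n_samples)),
        index=[f"p{i}" for i in range(n_probes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(data=data, stage=stage)
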