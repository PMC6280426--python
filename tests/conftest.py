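import numpy as np
import pandas as pd
import pytest

import coexsurv as cs


@pytest.fixture
def small_expression(tmp_path):
    """3-gene x 4-sample dense TSV fixture on disk, plus the expected frame."""
    df = pd.DataFrame(
        {
            "gene_id": ["EGFR", "NTN4", "ITGB4"],
            "s1": [1.0, 0.0, 3.5],
            "s2": [2.0, 1.0, 0.0],
            "s3": [0.0, 2.0, 1.0],
            "s4": [4.0, 3.0, 2.0],
        }
    )
    path = tmp_path / "expr.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path, df


@pytest.fixture
def cohort_frame():
    rng = np.random.default_rng(5)
    n = 92
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "time": rng.exponential(20.0, n).round(2),
            "event": rng.integers(0, 2, n),
            "EGFR": rng.normal(6, 1, n).round(3),
            "NTN4": rng.normal(5, 1, n).round(3),
        }
    )


@pytest.fixture
def cohort_path(tmp_path, cohort_frame):
    path = tmp_path / "cohort.tsv"
    cohort_frame.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def gmt_path(tmp_path):
    lines = [
        "GO:0001\tadhesion\tg1\tg2\tg3",
        "GO:0002\tECM organization\tg2\tg4\tg5\tg6",
    ]
    path = tmp_path / "sets.gmt"
    path.write_text("\n".join(lines) + "\n")
    return path
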