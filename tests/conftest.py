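import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix():
    """4 genes x 6 samples, two subsets of 3 replicates each."""
    from ptasig.stromal import ExpressionMatrix

    values = pd.DataFrame(
        {
            "FRC_1": [40.0, 4.0, 8.0, 1.0],
            "FRC_2": [44.0, 5.0, 8.0, 1.0],
            "FRC_3": [36.0, 6.0, 8.0, 1.0],
            "LEC_1": [4.0, 5.0, 8.0, 1.0],
            "LEC_2": [5.0, 5.0, 8.0, 1.0],
            "LEC_3": [6.0, 5.0, 8.0, 1.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    labels = pd.Series(
        ["FRC", "FRC", "FRC", "LEC", "LEC", "LEC"], index=values.columns
    )
    return ExpressionMatrix(values=values, sample_labels=labels)


@pytest.fixture
def small_ranked():
    """6-gene ranked list with distinct scores spanning both signs."""
    from ptasig.gsea import RankedList

    return RankedList(
        genes=("gA", "gB", "gC", "gD", "gE", "gF"),
        scores=np.array([3.0, 2.0, 1.0, -0.5, -1.5, -2.5]),
    )
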