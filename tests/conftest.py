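import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mzt.io_formats import StageExpressionMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_matrix(fpkm: dict[str, list[float]], stages: list[str]) -> StageExpressionMatrix:
    """One-sample-per-stage matrix from {gene: [fpkm per stage]}."""
    samples = [f"{s}_s" for s in stages]
    df = pd.DataFrame.from_dict(fpkm, orient="index", columns=samples).astype(float)
    return StageExpressionMatrix(df, dict(zip(samples, stages)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def triplet_matrix():
    """The five worked FPKM triples over GV/zygote/8-cell plus boundary genes."""
    return make_matrix(
        {
            "cluster1": [7, 0, 0],
            "cluster2": [7, 7, 0],
            "cluster3": [15, 3, 0],
            "cluster4": [7, 7, 7],
            "upregulated": [3, 15, 15],
            "boundary_gv": [2.0, 0, 0],
            "included_gv": [2.01, 2.01, 2.01],
        },
        ["GV", "zygote", "8-cell"],
    )
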