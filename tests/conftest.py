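import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from biocrustdiv.io import FeatureTable, SampleFrame
from biocrustdiv.simulate import SimParams, simulate_metacommunity


@pytest.fixture
def small_table():
    return FeatureTable(
        pd.DataFrame(
            [[6, 2, 0], [2, 2, 4], [10, 10, 10]],
            index=["s1", "s2", "s3"],
            columns=["t1", "t2", "t3"],
        )
    )


@pytest.fixture
def cherry_tree():
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def star_tree():
    return TreeNode.read(["(A:1,B:1,C:1,D:1);"])


def make_meta(n_sites=2, reps=2, stages=("A", "C", "M")):
    """Minimal hand-built metadata: sites 100 km apart, one env column
    per block."""
    rng = np.random.default_rng(0)
    rows, idx = [], []
    for site in range(n_sites):
        for stage in stages:
            for rep in range(reps):
                idx.append(f"s{site}{stage}{rep}")
                rows.append({
                    "site": f"site{site}",
                    "local_area": f"area{site // 2}",
                    "stage": stage,
                    "x_km": 100.0 * site,
                    "temp": 10 - site + rng.normal(0, 0.1),
                    "ph": 8 - 0.2 * "ACM".index(stage) + rng.normal(0, 0.05),
                    "chla": 1 + 0.5 * "ACM".index(stage) + rng.normal(0, 0.05),
                })
    return SampleFrame(
        pd.DataFrame(rows, index=idx),
        blocks={"climatic": ["temp"], "edaphic": ["ph"], "biotic": ["chla"]},
    )


@pytest.fixture
def tiny_meta():
    return make_meta()


#: reduced problem size for tests that only need the generator's
#: statistical structure, not its default scale
SMALL_SIM = dict(n_sites=6, pool_size=150, reads_per_sample=1000)


@pytest.fixture(scope="session")
def default_community():
    """One metacommunity drawn at the generator's default conditions."""
    return simulate_metacommunity(SimParams(seed=42))
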