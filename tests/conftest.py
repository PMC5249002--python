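import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # reference implementations

from obesinet.core import SOURCES
from obesinet.expression import ExpressionMatrix
from obesinet.simulate import SimConfig, fixture_reported_counts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_bundle():
    """The packaged reported-counts fixture (gene lists, counts, quality rows)."""
    return fixture_reported_counts()


@pytest.fixture(scope="session")
def small_sim():
    """A compact synthetic configuration used by slower end-to-end tests."""
    P, AV, AT, SY, GW = SOURCES
    return SimConfig(
        seed=7,
        n_genes=80,
        n_tissues=8,
        source_overlap_spec={
            (P,): 10, (AV,): 6, (AT,): 14, (SY,): 4, (GW,): 30,
            (P, AV): 3, (P, GW): 2, (AV, SY, GW): 1,
        },
        planted_categories={
            "Tissue_enriched": 5, "Group_enriched": 5, "Tissue_enhanced": 5,
            "Expressed_in_all": 5, "Mixed": 5, "Not_detected": 5,
        },
        planted_specific=(("T1", 8, 10.0),),
        clique_sizes=(6, 4),
    )


@pytest.fixture
def tiny_matrix():
    """4 genes x 3 tissues with one clearly tissue-specific gene."""
    frame = pd.DataFrame(
        [[9.0, 1.0, 1.0], [2.0, 2.0, 2.0], [1.0, 3.0, 2.0], [0.5, 0.5, 4.0]],
        index=["SPEC", "FLAT", "MIDDY", "LAST"],
        columns=["T1", "T2", "T3"],
    )
    return ExpressionMatrix(frame)
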