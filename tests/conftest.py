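import numpy as np
import pytest

from vacalibration import SimConfig
from vacalibration.types import CauseList


@pytest.fixture
def cl3():
    return CauseList("synthetic", ("cause_1", "cause_2", "cause_3"))


@pytest.fixture
def simconfig3():
    """Three-cause synthetic study with one probabilistic and one
    rank-based algorithm and a diagonally dominant truth."""
    M = np.array([[0.7, 0.2, 0.1],
                  [0.15, 0.7, 0.15],
                  [0.1, 0.2, 0.7]])
    return SimConfig(
        C=3, n_paired=500, n_survey=2000,
        p_survey=[0.5, 0.3, 0.2],
        p_calib_underlying=[0.25, 0.35, 0.4],
        immediate_kernel=np.array([[0.6, 0.25, 0.15],
                                   [0.2, 0.6, 0.2],
                                   [0.15, 0.25, 0.6]]),
        M_true={"insilicova": M, "eava": np.array([[0.6, 0.25, 0.15],
                                                   [0.2, 0.65, 0.15],
                                                   [0.15, 0.25, 0.6]])},
        concentration=25.0,
        p_inconclusive=0.15,
        seed=11,
    )
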