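import numpy as np
import pytest

from ethopipe import BehaviorLabel

S = BehaviorLabel.STANDING
LHU = BehaviorLabel.LHU
LHD = BehaviorLabel.LHD
ABS = BehaviorLabel.ABSENT


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def labels4():
    return [S, LHU, LHD, ABS]


def random_label_sequence(rng, n):
    return [BehaviorLabel(int(i)) for i in rng.integers(0, 4, n)]
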