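import numpy as np
import pytest

from optodrift import IonicParams, cell


@pytest.fixture(scope="session")
def params():
    return IonicParams()


@pytest.fixture(scope="session")
def rest_state(params):
    return cell.find_resting_state(params, 0.0)


@pytest.fixture(scope="session")
def templates(params):
    return cell.default_templates(params)


def activation_interp(t, v, thr=-20.0):
    idx = np.where((v[:-1] < thr) & (v[1:] >= thr))[0]
    return t[idx] + (thr - v[idx]) * (t[idx + 1] - t[idx]) / (v[idx + 1] - v[idx])
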