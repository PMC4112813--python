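import numpy as np
import pytest

import snrk1kin as sk


@pytest.fixture(scope="session")
def params():
    return sk.default_parameters()


@pytest.fixture(scope="session")
def snrk1(params):
    return params.snrk1


@pytest.fixture(scope="session")
def feeding_8h(params):
    """One shared 8 h feeding simulation with the shipped defaults."""
    return sk.integrate(params, protocol=sk.Protocol(t_end=8.0))


@pytest.fixture(scope="session")
def feeding_3h(params):
    return sk.integrate(params, protocol=sk.Protocol(t_end=3.0))


@pytest.fixture(scope="session")
def variant_steady(params):
    """Steady state of the invertase-modified variant (shared)."""
    pv = sk.make_steady_variant(params)
    res = sk.find_steady_state(pv, variant_label="invertase variant")
    return pv, res


def linear_r2(t, y, lo, hi):
    m = (t >= lo) & (t <= hi)
    x, yy = np.asarray(t)[m], np.asarray(y)[m]
    coef = np.polyfit(x, yy, 1)
    fit = np.polyval(coef, x)
    ss_res = float(np.sum((yy - fit) ** 2))
    ss_tot = float(np.sum((yy - yy.mean()) ** 2))
    return 1.0 - ss_res / ss_tot
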