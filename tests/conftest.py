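import numpy as np
import pytest

import wormloop as wl

#: Hand-chosen two-node parameters that oscillate near 1 Hz; used where a
#: deterministic oscillating circuit is needed without touching the fitted
#: fixtures.
HAND_TWO_NODE = dict(
    C_n=0.05, g_n=1.0, C_m=0.1, g_m=1.0, I_ext=40.0,
    w_che=1.0, syn_Vx=-30.0, syn_theta=5.0,
    w_f=1.0, fb_Vx=3.0, fb_theta=1.0,
    w_m=10.0, act_Vx=-30.0, act_theta=5.0,
    k=5.0, c=0.05, C_N=1.0, C_T=0.5,
)


@pytest.fixture(scope="session")
def two_node_params():
    return dict(HAND_TWO_NODE)


@pytest.fixture(scope="session")
def two_node_config(two_node_params):
    return wl.build_two_node_loop(two_node_params)


@pytest.fixture(scope="session")
def unit_params(two_node_params):
    p = dict(two_node_params)
    p.pop("I_ext")
    p.pop("w_che")
    p.pop("w_f")
    p.pop("fb_Vx")
    p.pop("fb_theta")
    p.update(
        u1=40.0, input_ratio=1.25,
        w_eM_d=1.0, w_eM_v=1.5, w_eI_d=1.0, w_eI_v=1.0,
        w_iM_d=1.0, w_iM_v=1.0, w_ii=0.5,
        w_nf_d=1.0, w_nf_v=1.0, nf_Vx=3.0, nf_theta=1.0,
    )
    return p


@pytest.fixture(scope="session")
def unit_config(unit_params):
    return wl.build_functional_unit(unit_params,
                                    input_ratio=unit_params["input_ratio"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
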