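import numpy as np
import pytest

import endoctrl as ec


@pytest.fixture(scope="session")
def table1():
    params, init = ec.load_default_base()
    return params, init


@pytest.fixture(scope="session")
def ia():
    sc = ec.preset("Ia")
    return sc, sc.params()


@pytest.fixture(scope="session")
def untreated_ia(ia):
    """Untreated extended-model trajectories and detected treatment starts."""
    sc, params = ia
    out = {}
    for diet in ("CD", "HFD"):
        traj = ec.integrate("extended", params, ec.initial_state(diet, sc),
                            (0.0, sc.t_f), grid_dt=0.05)
        t_tr = ec.detect_treatment_start(traj, params.eta, params.m1)
        out[diet] = (traj, t_tr)
    return out


@pytest.fixture(scope="session")
def coarse_problem(ia, untreated_ia):
    """26-node treatment-window problem (CD arm) for solver cross-checks."""
    sc, params = ia
    traj, t_tr = untreated_ia["CD"]
    state = np.maximum(traj.state_at(t_tr), 0.0)
    dt = (sc.t_f - t_tr) / 25
    return ec.OCPProblem(params=params, init=tuple(state), t0=t_tr,
                         tf=sc.t_f, grid_dt=dt)


@pytest.fixture(scope="session")
def zero_noise_data():
    return ec.default_experiment(seed=7, noise=ec.NoiseModel.noiseless())
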