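import numpy as np
import pytest

import flexkit as fk


@pytest.fixture(scope="session")
def coil():
    return fk.make_structure(fk.SyntheticSpec(kind="coil", n_res=40, seed=1))


@pytest.fixture(scope="session")
def helix():
    return fk.make_structure(fk.SyntheticSpec(kind="helix", n_res=30))


@pytest.fixture(scope="session")
def dumbbell():
    return fk.make_structure(fk.SyntheticSpec(kind="dumbbell", n_res=60,
                                              seed=0))


def spike_structure(state, n_res=150, res_start=1, missing=None, seed=0):
    spec = fk.SyntheticSpec(kind="pseudo_spike", n_res=n_res, chains="ABC",
                            res_start=res_start,
                            missing=missing or {},
                            state=tuple(state), seed=seed)
    return fk.make_structure(spec)


@pytest.fixture(scope="session")
def spike_states():
    """Small pseudo-spike trimers in the three canonical lobe states."""
    out = []
    for name in ("3down", "1up", "2up"):
        st = spike_structure(fk.spike_state_angles(name))
        st.title = name
        out.append(st)
    return out


@pytest.fixture(scope="session")
def dumbbell_anm(dumbbell):
    model = fk.ElasticModel(dumbbell.coords, cutoff=15.0)
    ms = fk.solve_modes(fk.build_hessian(model), n_modes=6)
    ms.source_atoms = dumbbell
    return ms


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
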