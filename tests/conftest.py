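import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.Philox(1234))


@pytest.fixture(scope="session")
def shell_pair_162():
    """Default-geometry shell pair at the desk-scale 162-node resolution."""
    from mpsim.mesh import make_sphere_mesh, pair_shells

    outer = make_sphere_mesh(162, 24.0, 3.1)
    inner = make_sphere_mesh(162, 16.0, 2.0)
    return pair_shells(outer, inner)


@pytest.fixture()
def tiny_state():
    """A 12-node shell pair plus a handful of dipoles, for force-level tests."""
    from mpsim.mesh import make_sphere_mesh, pair_shells
    from mpsim.state import NanoparticleEnsemble, SimulationState

    outer = make_sphere_mesh(12, 24.0, 3.1)
    inner = make_sphere_mesh(12, 16.0, 2.0)
    pair = pair_shells(outer, inner)
    g = np.random.Generator(np.random.Philox(7))
    pos = []
    while len(pos) < 6:
        u = g.standard_normal(3)
        u /= np.linalg.norm(u)
        cand = g.uniform(9.6, 9.85) * u
        if all(np.linalg.norm(cand - q) > 1.25 for q in pos):
            pos.append(cand)
    e = g.standard_normal((6, 3))
    e /= np.linalg.norm(e, axis=1, keepdims=True)
    ens = NanoparticleEnsemble(
        positions=np.array(pos), orientations=e, diameter=1.2, lambda_dd=3.0
    )
    return SimulationState(pair=pair, ensemble=ens, field_xi=2.0,
                           rng=np.random.Generator(np.random.Philox(11)))
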