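import numpy as np
import pytest

from valvenet.design import ValveDesignParams, build_valve
from valvenet.nurbs import KnotVector, NurbsSurface, open_uniform_knots


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def valve():
    return build_valve(ValveDesignParams())


@pytest.fixture
def quarter_cylinder():
    """Exact NURBS quarter cylinder, radius 1, height 2 (area pi/2 * 1 * 2)."""
    s2 = np.sqrt(2) / 2
    cp = np.array([[[1, 0, 0], [1, 0, 2]],
                   [[1, 1, 0], [1, 1, 2]],
                   [[0, 1, 0], [0, 1, 2]]], dtype=float)
    w = np.array([[1, 1], [s2, s2], [1, 1]], dtype=float)
    ku = KnotVector(np.array([0, 0, 0, 1, 1, 1.0]), 2)
    kv = KnotVector(np.array([0, 0, 1, 1.0]), 1)
    return NurbsSurface(cp, w, ku, kv, name="quarter_cylinder")


def random_surface(rng, m=None, n=None, degrees=(3, 3), rational=False):
    """Random smooth-ish patch: perturbed planar grid, optionally rational."""
    m = m or int(rng.integers(4, 8))
    n = n or int(rng.integers(4, 8))
    x, y = np.meshgrid(np.linspace(0, 2, m), np.linspace(0, 1.5, n), indexing="ij")
    cp = np.stack([x, y, 0.3 * rng.standard_normal((m, n))], axis=-1)
    cp += 0.05 * rng.standard_normal(cp.shape)
    w = rng.uniform(0.5, 2.0, (m, n)) if rational else np.ones((m, n))
    return NurbsSurface(cp, w, open_uniform_knots(m, degrees[0]),
                        open_uniform_knots(n, degrees[1]))


@pytest.fixture(scope="session")
def experiment():
    """Scaled-down end-to-end run shared by the expensive tests: 2,000
    surrogate closure simulations, 0.8/0.1/0.1 split, trained surrogate."""
    from valvenet.pipeline import run_experiment
    return run_experiment(seed=1, n_samples=2000)
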