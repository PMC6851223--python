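import numpy as np
import pytest

from fiberphantom import (
    Fiber,
    FiberGroup,
    ParametricDefinition,
    Phantom,
    eval_parametric,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


@pytest.fixture
def helix():
    """Unit-radius helix along z (the classic parametric test object)."""
    return eval_parametric(
        ParametricDefinition("sin(t)", "cos(t)", "t", "1", 0.0, 20.0, 200),
        label="helix",
    )


@pytest.fixture
def cone_envelope():
    """Straight envelope whose radius doubles along its length."""
    n = 21
    z = np.linspace(0.0, 100.0, n)
    data = np.column_stack([np.zeros(n), np.zeros(n), z, 10.0 + z / 10.0])
    return Fiber(data, label="cone")


@pytest.fixture
def straight_envelope():
    """Straight constant-radius cylinder envelope along z."""
    n = 11
    z = np.linspace(0.0, 100.0, n)
    data = np.column_stack([np.zeros(n), np.zeros(n), z, np.full(n, 10.0)])
    return Fiber(data, label="cylinder")


def random_smooth_fiber(rng, n_controls=6, n_samples=40, scale=50.0):
    """A random smooth fiber built from a spline through random controls."""
    from fiberphantom import interpolate_spline

    while True:
        ctrl = np.column_stack(
            [
                np.sort(rng.uniform(0, scale, n_controls)),
                rng.uniform(-scale / 2, scale / 2, n_controls),
                rng.uniform(-scale / 2, scale / 2, n_controls),
                rng.uniform(1.0, 5.0, n_controls),
            ]
        )
        if np.all(np.diff(ctrl[:, 0]) > 1e-3):
            break
    sps = max(1, n_samples // (n_controls - 1))
    return interpolate_spline(ctrl, sps)


@pytest.fixture
def small_phantom():
    """Three parallel straight fibers in one group."""
    group = FiberGroup("trio")
    for i in range(3):
        data = np.array([[i * 10.0, 0.0, 0.0, 1.0], [i * 10.0, 0.0, 50.0, 1.0]])
        group.add(Fiber(data, label=f"f{i}"))
    p = Phantom()
    p.add(group)
    return p
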