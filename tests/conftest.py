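import numpy as np
import pytest

from memrod import (MembraneParams, ParticleState, RodSpec, SimulationBox,
                    FlatSpec, build_flat_patch)


@pytest.fixture(scope="session")
def params():
    """Canonical calibrated membrane parameters."""
    return MembraneParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_patch():
    """100-particle flat membrane patch (deterministic)."""
    return build_flat_patch(FlatSpec(n=100), seed=0)


def random_membrane_state(rng, n=20, box_side=8.0, z_amp=0.5):
    """Loose random configuration (no deep overlaps) for gradient tests."""
    pos = rng.uniform(0, box_side, (n, 3))
    pos[:, 2] = rng.uniform(-z_amp, z_amp, n)
    # push apart anything closer than 0.9 sigma
    for _ in range(200):
        d = pos[:, None, :] - pos[None, :, :]
        r = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(r, np.inf)
        i, j = np.unravel_index(np.argmin(r), r.shape)
        if r[i, j] > 0.9:
            break
        shift = d[i, j] / (r[i, j] + 1e-12) * (0.9 - r[i, j] + 0.05)
        pos[i] += 0.5 * shift
        pos[j] -= 0.5 * shift
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return ParticleState.membrane_only(pos, u), SimulationBox(
        [box_side, box_side, 40.0], "flat")
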