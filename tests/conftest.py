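import numpy as np
import pytest

from solentile import (
    SolenoidSpec,
    build_solenoid,
    model_from_arrays,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_coil_model(n, seed, step=3.8, stiffness=0.9):
    """Self-avoiding random walk Cα trace with a random sequence."""
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    d = np.array([1.0, 0.0, 0.0])
    for _ in range(n - 1):
        for _ in range(500):
            prop = stiffness * d + rng.normal(size=3)
            prop /= np.linalg.norm(prop)
            new = pts[-1] + step * prop
            if all(np.linalg.norm(new - q) > 3.5 for q in pts[:-1]):
                break
        pts.append(new)
        d = prop
    seq = "".join(np.random.default_rng(seed + 1).choice(list(AA20), n))
    return model_from_arrays(seq, np.array(pts), source_id=f"coil{seed}")


def rotated_copy(model, chain_id="A", angle=0.9, axis=(0.3, -0.5, 0.8),
                 shift=(11.0, -3.0, 7.0)):
    """The same chain after an arbitrary global rigid transform."""
    ax = np.asarray(axis, dtype=float)
    ax /= np.linalg.norm(ax)
    K = np.array(
        [[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    ca = model.ca_coords(chain_id) @ R.T + np.asarray(shift)
    cb = model.cb_coords(chain_id) @ R.T + np.asarray(shift)
    return model_from_arrays(model.sequence(chain_id), ca, cb,
                             source_id=model.source_id + "-rot")


@pytest.fixture(scope="session")
def perfect_solenoid():
    """Noise-free, mutation-free 4-unit solenoid with period 33."""
    model, truth = build_solenoid(
        SolenoidSpec(unit_length=33, n_units=4, noise_sd=0.0,
                     mutation_rate=0.0, seed=0)
    )
    return model, truth


@pytest.fixture(scope="session")
def noisy_solenoid():
    """Realistic 6-unit solenoid: 0.3 A coordinate noise, 10% mutations."""
    model, truth = build_solenoid(
        SolenoidSpec(unit_length=33, n_units=6, noise_sd=0.3,
                     mutation_rate=0.1, seed=2)
    )
    return model, truth


@pytest.fixture(scope="session")
def coil130():
    return random_coil_model(130, seed=0)
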