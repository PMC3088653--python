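import numpy as np
import pytest

from protrusim.model_core import ContourState, FlatState, ModelParams


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


def make_flat_state(N=64, L=20.0, amp=0.1, phi_amp=0.03, seed=0,
                    phi_bar=0.1) -> FlatState:
    """Smooth low-mode flat state for force/flux tests."""
    rng = np.random.default_rng(seed)
    dx = L / N
    x = np.arange(N) * dx
    h = np.zeros(N)
    phi = np.full(N, phi_bar)
    for k in (1, 2, 3, 5):
        h += amp * rng.normal() / k * np.cos(2 * np.pi * k * x / L
                                             + rng.uniform(0, 2 * np.pi))
        phi += phi_amp * rng.normal() / k * np.cos(2 * np.pi * k * x / L
                                                   + rng.uniform(0, 2 * np.pi))
    return FlatState(x=x, h=h, phi=np.clip(phi, 0.01, 0.99), L_init=L)


def make_round_state(N=256, R=3.0, amp=0.05, phi_amp=0.03, seed=0,
                     phi_bar=0.1) -> ContourState:
    """Smooth perturbed circle for force/flux tests."""
    rng = np.random.default_rng(seed)
    theta = 2 * np.pi * np.arange(N) / N
    r = np.full(N, R)
    phi = np.full(N, phi_bar)
    for k in (2, 3, 5):
        r += amp * R * rng.normal() / k * np.cos(k * theta
                                                 + rng.uniform(0, 2 * np.pi))
        phi += phi_amp * rng.normal() / k * np.cos(k * theta
                                                   + rng.uniform(0, 2 * np.pi))
    nodes = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return ContourState(nodes=nodes, phi=np.clip(phi, 0.01, 0.99),
                        A_pref=np.pi * R ** 2, L_init=2 * np.pi * R)
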