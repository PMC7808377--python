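import numpy as np
import pytest

from laminachain import ModelParams, SweepSchedule


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def short_schedule(total=100_000, pre=10_000, every=1_000) -> SweepSchedule:
    return SweepSchedule(total_sweeps=total, pre_equilibration_sweeps=pre,
                         sample_every=every)


@pytest.fixture
def plausible_states():
    """Thermally plausible perturbed chain states for energy oracles:
    initialized geometry plus small Gaussian displacements of free beads
    (no deep excluded-volume overlaps)."""
    from laminachain import initialize_chain

    def make(params: ModelParams, n_states: int, seed: int = 0,
             scale: float = 1.5):
        rng = np.random.default_rng(seed)
        states = []
        for _ in range(n_states):
            st = initialize_chain(params)
            st.coords[1:] += rng.normal(0.0, scale,
                                        size=(params.n_beads - 1, 3))
            states.append(st)
        return states

    return make
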