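import numpy as np
import pandas as pd
import pytest

from sealars import simulate


@pytest.fixture(scope="session")
def grey_profile():
    return simulate.species_profile("grey", movement_states_only=True)


@pytest.fixture(scope="session")
def grey_movement_intervals():
    """10 movement-only grey-seal tracks of 400 intervals each."""
    cfg = simulate.SimulationConfig(
        n_individuals=10, n_intervals_per_individual=400,
        species_profile="grey", movement_states_only=True, seed=314)
    return simulate.tracks_to_intervals(simulate.simulate_hmm_tracks(cfg))


@pytest.fixture(scope="session")
def five_state_intervals():
    """Small five-state simulation with known-state codes and gaps."""
    cfg = simulate.SimulationConfig(
        n_individuals=4, n_intervals_per_individual=120,
        species_profile="grey", movement_states_only=False,
        gap_rate=0.04, seed=99)
    return simulate.tracks_to_intervals(simulate.simulate_hmm_tracks(cfg))


@pytest.fixture(scope="session")
def seascape():
    return simulate.build_seascape(seed=3)


def random_toy_instance(rng, T, K, with_mask=True, with_missing=True):
    """A random small HMM instance for enumeration oracles."""
    from sealars.hmm import HMMParameters, _STATE_SETS

    states = _STATE_SETS[K][:K] if K in (1, 2, 3) else tuple(f"s{i}" for i in range(K))
    mu = rng.uniform(0.3, 8.0, K)
    sigma = mu * rng.uniform(0.3, 1.2, K)
    conc = rng.uniform(0.0, 0.9, K)
    tpm = rng.dirichlet(np.ones(K) * 2, size=K)
    delta = rng.dirichlet(np.ones(K))
    params = HMMParameters(states, mu, sigma, conc, tpm, delta)
    z = rng.integers(0, K, size=T)
    steps = rng.gamma(2.0, 1.5, size=T)
    angles = rng.uniform(-np.pi, np.pi, size=T)
    if with_missing:
        steps[rng.random(T) < 0.2] = np.nan
        angles[rng.random(T) < 0.2] = np.nan
    codes = ["free"] * T
    if with_mask:
        for t in range(T):
            if rng.random() < 0.3:
                codes[t] = states[z[t]]
    df = pd.DataFrame({"individual": "a", "step": steps, "angle": angles,
                       "known_state": codes})
    return df, params
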