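import numpy as np
import pytest

from fretbind.scheme import KineticScheme, Photophysics, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def two_state_scheme():
    """U <-> B with k_on = k_off = 0.5 /s, bound FRET 0.7."""
    return KineticScheme(
        state_names=("U", "B"),
        fret_mean=np.array([0.0, 0.7]),
        rate_matrix=np.array([[0.0, 0.5], [0.5, 0.0]]),
    )


@pytest.fixture
def noiseless_photophysics():
    return Photophysics(total_intensity=1000.0, background=0.0,
                        read_noise_sd=0.0, shot_noise_scale=0.0,
                        donor_bleach_rate=0.0, acceptor_bleach_rate=0.0)


@pytest.fixture(scope="session")
def scenario_runs():
    """Session cache of full closed-loop recovery runs, keyed by scenario.

    All acceptance-scale runs share this cache so each scenario is
    simulated and analyzed exactly once per test session.
    """
    from fretbind.pipeline import recover_scenario

    cache: dict[str, dict] = {}

    def get(name: str, n_molecules: int = 100, seed: int = 1):
        key = f"{name}:{n_molecules}:{seed}"
        if key not in cache:
            cache[key] = recover_scenario(name, n_molecules=n_molecules,
                                          seed=seed)
        return cache[key]

    return get


def make_config(scheme, n_molecules=10, max_duration=30.0, seed=0, **ph_kwargs):
    return SimConfig(
        scheme=scheme,
        photophysics=Photophysics(**ph_kwargs) if ph_kwargs else Photophysics(),
        n_molecules=n_molecules,
        max_duration=max_duration,
        rng_seed=seed,
    )
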