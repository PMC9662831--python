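import pytest
from hypothesis import settings

import parahop as ph
from parahop.synth import SyntheticSpec

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def fig4_params():
    return ph.preset("fig4")


@pytest.fixture(scope="session")
def ou_track_long():
    """Exact OU track at the experimentally fitted magnitudes, long enough
    for tight estimator checks."""
    spec = SyntheticSpec(
        kind="ou", D=2.27e-4, tau=120.0, dt_sample=60.0, n_steps=100_000,
        seed=11, cell_length=10.0,
    )
    return spec, ph.gen_ou(spec)


@pytest.fixture(scope="session")
def small_sim(fig4_params):
    """One short full-scale simulation at the fitted point, reused by
    cheap sanity checks."""
    return ph.run(fig4_params, duration=600.0, burn_in=300.0,
                  sampling_interval=60.0, seed=5)
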