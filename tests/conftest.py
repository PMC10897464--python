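import pytest

from perilipid.phantom import PhantomSpec, echo_times_ms, generate_phantom
from perilipid.spectral import TriglycerideSpectrum


@pytest.fixture(scope="session")
def spectrum():
    return TriglycerideSpectrum()


@pytest.fixture(scope="session")
def te16():
    return echo_times_ms(16)


def small_spec(**kw) -> PhantomSpec:
    """Desk-scale phantom: 24x24x10 grid, 7 mm tumour."""
    defaults = dict(grid_shape=(24, 24, 10),
                    breast_semiaxes_mm=(40.0, 70.0, 18.0),
                    chest_wall_mm=15.0,
                    tumour_radius_mm=7.0,
                    seed=42)
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def truth_small():
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def truth_control():
    return generate_phantom(small_spec(tumour_radius_mm=0.0,
                                       rim_effect_amplitude=0.0))
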