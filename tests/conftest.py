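import numpy as np
import pytest

from lamdiff import (
    InstrumentConfig,
    SampleCondition,
    build_profile,
    fixture_preset,
    structure_factors_from_profile,
    synth_diffractogram,
)


@pytest.fixture(scope="session")
def instrument():
    return InstrumentConfig()


@pytest.fixture(scope="session")
def ctx(instrument):
    return instrument.correction_context()


@pytest.fixture(scope="session")
def render():
    """Render a preset diffractogram: render(label, temp, rh, noise, seed)."""
    instrument = InstrumentConfig()

    def _render(label, temp=70.0, rh=95.0, noise="none", seed=0, d2o=0.08,
                n_orders=None, counts_scale=None):
        inst = instrument
        if counts_scale is not None:
            inst = InstrumentConfig(counts_scale=counts_scale)
        cond = SampleCondition(temp, rh, d2o)
        spec = fixture_preset(label, cond)
        if n_orders is not None:
            spec.n_orders = n_orders
        profile = build_profile(spec, 512)
        sf = structure_factors_from_profile(profile, spec.n_orders)
        sf.metadata.update({"label": label, **cond.to_dict()})
        diff = synth_diffractogram(sf, inst, noise=noise, seed=seed)
        return spec, sf, diff

    return _render


@pytest.fixture(autouse=True)
def _quiet_warnings():
    # merged-candidate / missing-order warnings are expected in stress tests
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def rng(seed=0):
    return np.random.default_rng(seed)
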