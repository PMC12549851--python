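import numpy as np
import pytest

import emdsel as E


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def blackbody_data():
    """Planck-generated long-wavelength dataset with a small sensor bias."""
    return E.generate_blackbody_data(
        n_points=1024, b0=0.0015, law="planck",
        rng=np.random.default_rng(101),
    )


@pytest.fixture(scope="session")
def planck_candidate(blackbody_data):
    return E.BlackBodyCandidate("planck").fit(*blackbody_data.xy)


@pytest.fixture(scope="session")
def rj_candidate(blackbody_data):
    return E.BlackBodyCandidate("rayleigh-jeans").fit(*blackbody_data.xy)


@pytest.fixture(scope="session")
def planck_spec(blackbody_data, planck_candidate):
    """HB process spec for the Planck candidate at c = 2^-2."""
    mixed, synth = E.mixed_and_synthetic_ppfs(
        planck_candidate, blackbody_data, rng=np.random.default_rng(102)
    )
    return E.HBProcessSpec(
        mixed_ppf=mixed, discrepancy=E.delta_emd(mixed, synth), c=0.25
    )


@pytest.fixture
def spec_factory(planck_spec):
    """Same PPF pair as planck_spec but at arbitrary sensitivity c."""

    def make(c, **kwargs):
        return E.HBProcessSpec(
            mixed_ppf=planck_spec.mixed_ppf,
            discrepancy=planck_spec.discrepancy,
            c=c,
            **kwargs,
        )

    return make
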