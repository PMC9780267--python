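import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_db():
    from saponet import load_reference_db

    return load_reference_db()


@pytest.fixture(scope="session")
def ref_spectra(ref_db):
    from saponet import db_to_spectra

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # two records have no fragments
        return db_to_spectra(ref_db)


@pytest.fixture(scope="session")
def rule_set():
    from saponet import default_rules

    return default_rules()
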