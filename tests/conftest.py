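import pytest

from preecon.costing import load_inpatient_groups, load_service_catalog
from preecon.parameters import base_case_path, load_config


@pytest.fixture(scope="session")
def base_config():
    return load_config(base_case_path())


@pytest.fixture()
def base_doc(base_config):
    """A fresh mutable copy of the base-case document."""
    from preecon.parameters import serialize_config

    return serialize_config(base_config)


@pytest.fixture(scope="session")
def catalog():
    return load_service_catalog()


@pytest.fixture(scope="session")
def inpatient_groups():
    return load_inpatient_groups()
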