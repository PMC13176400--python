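import pytest

from sybodykit import design as dmod
from sybodykit.assembly import CodonTable, build_cassette


@pytest.fixture(scope="session")
def s10():
    return dmod.load_s10()


@pytest.fixture(scope="session")
def s10_template(s10):
    return build_cassette(s10)


@pytest.fixture(scope="session")
def ecoli_table():
    return CodonTable.ecoli()


@pytest.fixture(scope="session")
def toy_design():
    """Tiny two-position design: diversity 2 x 3 = 6."""
    return dmod.design_from_dict({
        "name": "toy",
        "scaffold": "MKTAYIAKQRQISFVKSHFSRQLE",
        "regions": [
            {"name": "FR1", "start": 0, "end": 8},
            {"name": "CDR1", "start": 8, "end": 12},
            {"name": "FR2", "start": 12, "end": 18},
            {"name": "CDR2", "start": 18, "end": 20},
            {"name": "FR3", "start": 20, "end": 24},
        ],
        "compositions": [
            {"position": 9, "allowed": {"A": 0.5, "V": 0.5}},
            {"position": 10, "allowed": ["A", "V", "L"]},
        ],
    })
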