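import pytest

from crnregions import fixtures, run_procedure
from crnregions.fixtures import OVERRIDES


@pytest.fixture(scope="session")
def nets():
    return fixtures()


@pytest.fixture(scope="session")
def traces(nets):
    """Full procedure traces for all six fixtures (overrides applied)."""
    out = {}
    for name, net in nets.items():
        ov = OVERRIDES.get(name, {})
        out[name] = run_procedure(
            net, omega=ov.get("omega"), split=ov.get("split")
        )
    return out
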