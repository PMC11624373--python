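import pytest

from crtdcost import builtin_base_case


@pytest.fixture(scope="session")
def base_case():
    return builtin_base_case()
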