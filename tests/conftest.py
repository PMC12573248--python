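import pytest

from ghostshift import (
    AcceptorWindow,
    FixtureSpec,
    make_fixture_space,
    symmetric_fixture,
)

#: eukaryogenesis acceptor window used across fixtures (ages in Ga)
FECA, LECA = 2.42, 1.89


@pytest.fixture
def window():
    return AcceptorWindow(feca_age=FECA, leca_age=LECA)


@pytest.fixture
def symmetric_space():
    """Single donor branch born at the older window bound: P(shift) = 1/4."""
    space, window = make_fixture_space(symmetric_fixture())
    return space, window


@pytest.fixture
def two_clade_fixture():
    """Two donor branches with distinct clade labels, both alive today."""
    return FixtureSpec(
        feca_age=FECA,
        leca_age=LECA,
        branches=((3.0, 0.0, "P"), (2.41, 0.0, "Q")),
    )


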