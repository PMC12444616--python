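import pytest

from cubioleach import (
    BioKinetics,
    ChemKinetics,
    ColumnGeometry,
    InflowProgram,
    LoopConfig,
)


@pytest.fixture
def geom() -> ColumnGeometry:
    return ColumnGeometry()


@pytest.fixture
def chem() -> ChemKinetics:
    return ChemKinetics()


@pytest.fixture
def bio() -> BioKinetics:
    return BioKinetics()


@pytest.fixture
def loop() -> LoopConfig:
    return LoopConfig()


@pytest.fixture
def ferric_feed() -> InflowProgram:
    """The standard ~10 g/L ferric leaching solution."""
    return InflowProgram.ferric_feed(10.0)
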