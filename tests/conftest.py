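import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from bromscreen.chem import AtomicMassTable, IonSpecies, parse_formula
from bromscreen.simulate import default_targets, make_run


@pytest.fixture(scope="session")
def table():
    return AtomicMassTable.default()


@pytest.fixture(scope="session")
def targets():
    return default_targets()


def deprotonated(formula: str, k81: int = 0) -> IonSpecies:
    ion = IonSpecies(parse_formula(formula), "[M-H]-")
    return ion.substituted("Br", "81Br", k81) if k81 else ion


@pytest.fixture(scope="session")
def standard_run():
    """One run with all three analytes at mid-range concentration."""
    return make_run({"TBBPS-MAE": 5.0, "TBBPS-MBAE": 5.0, "TBBPS-MDBPE": 2.0},
                    seed=7)


@pytest.fixture(scope="session")
def blank_run():
    return make_run({}, seed=3)
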