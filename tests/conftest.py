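import numpy as np
import pytest

from icrcell import IonCloudSpec, evaluate_trap
from icrcell.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def cloud():
    return IonCloudSpec()


@pytest.fixture(scope="session")
def cubic_row():
    return evaluate_trap("cubic")


@pytest.fixture(scope="session")
def cylindrical_row():
    return evaluate_trap("cylindrical")


@pytest.fixture(scope="session")
def hyperbolic_row():
    return evaluate_trap("hyperbolic")


@pytest.fixture(scope="session")
def open_compensated_row():
    return evaluate_trap("open_compensated")


@pytest.fixture(scope="session")
def paracell_row():
    return evaluate_trap("paracell")


@pytest.fixture(scope="session")
def all_rows(cubic_row, cylindrical_row, hyperbolic_row, open_compensated_row,
             paracell_row):
    rows = {r.trap: r for r in (cubic_row, cylindrical_row, hyperbolic_row,
                                open_compensated_row, paracell_row)}
    for kind in ("hyperbolic_compensated", "cuboid", "cylindrical_compensated",
                 "tolmachev", "brustkern"):
        rows[kind] = evaluate_trap(kind)
    return rows
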