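import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cocult.fba import apply_medium_constraints
from cocult.synthetic import ToySpec, make_toy_cell_model


@pytest.fixture(scope="session")
def stromal_cell():
    """Toy stromal-like cell: (model, etc_map, thermo_table, medium)."""
    return make_toy_cell_model(ToySpec(), "stromal_like")


@pytest.fixture(scope="session")
def myeloma_cell():
    return make_toy_cell_model(ToySpec(), "myeloma_like")


@pytest.fixture(scope="session")
def stromal_constrained(stromal_cell):
    """Stromal cell with its medium applied."""
    model, etc, thermo, medium = stromal_cell
    return apply_medium_constraints(model, medium), etc


@pytest.fixture(scope="session")
def myeloma_constrained(myeloma_cell):
    model, etc, thermo, medium = myeloma_cell
    return apply_medium_constraints(model, medium), etc
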