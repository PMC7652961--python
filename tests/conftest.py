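import pytest

from ritdose import io as rio
from ritdose.pipeline import celldose_report


@pytest.fixture(scope="session")
def s_table():
    """Packaged cellular S-value table (monolayer PANC-1 geometry)."""
    return rio.read_cell_svalues()


@pytest.fixture(scope="session")
def table1_tia():
    """Worked-example per-compartment TIAs for the three conjugates."""
    return rio.read_cell_tia()


@pytest.fixture(scope="session")
def worked_example(table1_tia, s_table):
    """Full cellular-dose report for the packaged worked example."""
    return celldose_report(table1_tia, s_table)
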