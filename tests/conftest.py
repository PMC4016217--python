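import pytest

from habvalue.survey_data import OccupancySeries, Status, SurveyRecord
from habvalue.synthetic_data import SimulationConfig, simulate_metapopulation

OCC, UNOCC, UNK = Status.OCCUPIED, Status.UNOCCUPIED, Status.UNKNOWN


def series(site_id, substrate, statuses):
    return OccupancySeries(site_id=site_id, substrate=substrate, statuses=statuses)


@pytest.fixture(scope="session")
def sim_small():
    """One modest simulated survey (shared across tests; read-only)."""
    cfg = SimulationConfig(n_sites=40, seed=11)
    return simulate_metapopulation(cfg)


@pytest.fixture
def portal_csv(tmp_path):
    """Three-row toy portal table: occupied / unoccupied / blank status."""
    path = tmp_path / "portal.csv"
    path.write_text(
        "site_id,year,substrate,status,n_breeding_birds,n_nests,n_fledglings\n"
        "A,2005,Cattails,occupied,150,100,100\n"
        "A,2006,Cattails,unoccupied,,,\n"
        "B,2006,triticale,,,,\n"
    )
    return path
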