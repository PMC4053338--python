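from datetime import date, datetime

import pytest

from carrion import simulate
from carrion.data import BiomassInspection, CarcassSite, VisitEvent


@pytest.fixture(scope="session")
def fixture_study():
    """The packaged deterministic 30-carcass study."""
    return simulate.packaged_fixture()


@pytest.fixture
def small_site():
    return CarcassSite(
        carcass_id="T01C1",
        transect_id=1,
        distance_to_farm=0.05,
        season="winter",
        deploy_date=date(2012, 5, 1),
        removal_date=date(2012, 5, 10),
    )


@pytest.fixture
def small_inspections(small_site):
    return [
        BiomassInspection(small_site.carcass_id, date(2012, 5, 1), 1.0, 1.0),
        BiomassInspection(small_site.carcass_id, date(2012, 5, 15), 0.6, 0.7),
    ]


def make_event(cid="T01C1", species="wild_dog", when=None, dur_s=600.0,
               behaviour="feeding"):
    return VisitEvent(
        carcass_id=cid,
        species=species,
        start_time=when or datetime(2012, 5, 3, 18, 0),
        duration=dur_s,
        behaviour=behaviour,
    )
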