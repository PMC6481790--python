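import pytest

from turtletow.io import Region, SegmentObservation, Species
from turtletow.simulate import (
    CountSpec,
    RegionSpec,
    SimulationConfig,
    simulate_survey,
)


def seg(site="PRIA-01", year=2002, tow="T1", idx=1, species=Species.GREEN, count=0,
        length=None, region=Region.PRIA, seg_len=220.0):
    return SegmentObservation(
        region=region, site_id=site, year=year, tow_id=tow, segment_index=idx,
        segment_length_m=seg_len, species=species, count=count, mean_length_cm=length,
    )


@pytest.fixture
def tiny_segments():
    """Three survey years at one site, including zeros and both species."""
    rows = []
    for year in (2002, 2004, 2006):
        rows += [
            seg(year=year, tow=f"{year}-T1", idx=1, count=0),
            seg(year=year, tow=f"{year}-T1", idx=2, species=Species.GREEN, count=2, length=50),
            seg(year=year, tow=f"{year}-T1", idx=3, species=Species.HAWKSBILL, count=1, length=40),
        ]
    return rows


@pytest.fixture(scope="session")
def small_survey():
    """A compact two-region synthetic survey with known generating values."""
    config = SimulationConfig(
        regions=(
            RegionSpec(Region.PRIA, 3, (2002, 2004, 2006, 2008), density_per_1000=250.0,
                       site_spread=0.3, growth_rate=0.0),
            RegionSpec(Region.HIIS, 4, (2002, 2004, 2006, 2008), density_per_1000=40.0,
                       site_spread=0.3, growth_rate=0.05),
        ),
        tows_per_survey=4,
        count=CountSpec(family="negbin", k=0.7),
        seed=42,
    )
    segments, sites, truth = simulate_survey(config)
    return config, segments, sites, truth
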