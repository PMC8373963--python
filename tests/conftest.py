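import numpy as np
import pytest

from aphidweb.io import DetectionRecord
from aphidweb.simulate import SimulationConfig, generate_study


def rec(site, year, sid, primary, hyper=()):
    return DetectionRecord(
        site_id=site,
        year=year,
        sample_id=sid,
        primary_species=primary,
        hyper_species=tuple(hyper),
    )


@pytest.fixture
def small_records():
    """Three mummies: two webs links on P1xH1, one on P2xH2, one unattacked."""
    return [
        rec("A", 2014, "m1", "P1", ["H1"]),
        rec("A", 2014, "m2", "P1", ["H1"]),
        rec("A", 2014, "m3", "P2", ["H2"]),
        rec("A", 2014, "m4", "P1"),
    ]


@pytest.fixture(scope="session")
def default_bundle():
    """One 25-site-year synthetic study at the default conditions."""
    return generate_study(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def recovery_bundle():
    """A 500-site-year study for parameter-recovery checks."""
    return generate_study(SimulationConfig(seed=0, n_sites=500))
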