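import numpy as np
import pytest

from dntprio.bmc import ResponseSeries
from dntprio.pbtk import ChemicalTKParams, load_physiology
from dntprio.synthetic import default_design


def make_series(concs, means, endpoint_class="dnt", chemical="chem",
                assay="assay", endpoint="ep"):
    """Single-replicate series with the given per-concentration responses."""
    records = tuple((float(c), float(r), "r0") for c, r in zip(concs, means))
    return ResponseSeries(chemical_id=chemical, assay_id=assay,
                          endpoint_id=endpoint, endpoint_class=endpoint_class,
                          records=records,
                          max_tested=float(max(c for c in concs if c > 0)))


@pytest.fixture
def design():
    return default_design()


@pytest.fixture
def chem():
    return ChemicalTKParams(chemical_id="demo", mw=300.0, fup=0.2, clint=5.0,
                            logp=3.0)


@pytest.fixture(scope="session")
def child_phys():
    return load_physiology("human_child")


@pytest.fixture(scope="session")
def rat_phys():
    return load_physiology("rat")
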