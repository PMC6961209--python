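import numpy as np
import pytest

from mtpipe import helical_geometry as hg
from mtpipe.star_io import make_table


@pytest.fixture(scope="session")
def params13():
    return hg.helical_table(13, 3)


@pytest.fixture(scope="session")
def params16():
    return hg.helical_table(16, 4)


@pytest.fixture(scope="session")
def lattice13(params13):
    """Decorated 13-3 lattice long enough to span a 600 Å box diagonally."""
    return hg.build_lattice(params13, 900.0, decorated=True, seam_pf=0)


@pytest.fixture(scope="session")
def lattice13_bare(params13):
    return hg.build_lattice(params13, 900.0, decorated=False, seam_pf=0)


@pytest.fixture()
def blank_table():
    def _make(n, **kw):
        return make_table(n, **kw)
    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
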