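import numpy as np
import pytest

from facseg import FuzzyActiveContour, LocalFuzzyActiveContour
from facseg.synthetic import default_suite, make_ramp_ring


@pytest.fixture(scope="session")
def clean_scene():
    """Clean ramp-ring scene (image, ground-truth mask)."""
    return make_ramp_ring()


@pytest.fixture(scope="session")
def suite_fits():
    """FAC and LFAC fitted on the four default scenes (shared: expensive)."""
    out = {}
    for name, (img, truth, spec) in default_suite(seed=0).items():
        fac = FuzzyActiveContour(img).fit()
        lfac = LocalFuzzyActiveContour(img).fit()
        out[name] = {"image": img, "truth": truth, "fac": fac, "lfac": lfac}
    return out


@pytest.fixture(scope="session")
def clean_lfac(suite_fits):
    return suite_fits["clean"]["lfac"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
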