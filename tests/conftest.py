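import numpy as np
import pytest

from promspec.pb import PBParameters, build_hessian, diagonalize
from promspec.regions import detect_regions
from promspec.seqio import PromoterRecord, encode_ws


@pytest.fixture(scope="session")
def default_params():
    return PBParameters()


def detect(record: PromoterRecord, **kwargs):
    """Full detection pipeline for one promoter (shared helper)."""
    spectrum = diagonalize(build_hessian(encode_ws(record.sequence)))
    return detect_regions(spectrum, record, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n, bases="ACGT"):
    return "".join(rng.choice(list(bases), size=n))
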