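import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pival import FragmentationParams, PSM, SequestHit, Spectrum, Peak
from pival.synth import default_true_params

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def identity_params():
    """All-ones propensities/position factors, zero loss probabilities."""
    return FragmentationParams.identity()


@pytest.fixture
def true_params():
    """The simulator's fixed ground-truth parameters."""
    return default_true_params()


@pytest.fixture
def rng():
    return np.random.default_rng(2011)


def make_psm(spectrum: Spectrum, peptide: str, xcorr: float = 3.0,
             delta_cn: float = 0.3, proteins=None) -> PSM:
    hit = SequestHit(rank=1, peptide=peptide, flank_prev="K", flank_next="A",
                     xcorr=xcorr, delta_cn=delta_cn, sp=100.0,
                     proteins=proteins or ["SYNP00000"])
    return PSM(spectrum=spectrum, hit=hit,
               is_decoy=any(p.startswith("rev_") for p in hit.proteins))


@pytest.fixture
def psm_factory():
    return make_psm


@pytest.fixture
def simple_spectrum():
    return Spectrum(source_id="s1", precursor_mh=500.0, charge=2,
                    peaks=[Peak(100.0, 10.0), Peak(200.0, 20.0)])
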