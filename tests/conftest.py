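import numpy as np
import pytest

from rbldesign.fixtures import (beta_hairpin, helix_with_cap,
                                make_planted_bidentate, turn_fragment,
                                two_cluster_fragments, TURN_TYPES)
from rbldesign.geometry_core import HelixParams, SixDOF, make_ideal_helix
from rbldesign.hbond_geometry import place_amide_hydrogens
from rbldesign.repeat_backbone import RepeatSpec, build_repeat_backbone


@pytest.fixture(scope="session")
def ideal_helix14():
    return make_ideal_helix(HelixParams(length=14))


@pytest.fixture(scope="session")
def hairpin():
    return beta_hairpin()


@pytest.fixture(scope="session")
def turn_gallery():
    return {t: turn_fragment(t) for t in TURN_TYPES}


@pytest.fixture(scope="session")
def capped_helix():
    return helix_with_cap()


@pytest.fixture(scope="session")
def cluster_fragments():
    return two_cluster_fragments(n=12, seed=3)


@pytest.fixture(scope="session")
def demo_spec():
    """The packaged demo repeat geometry: a staggered two-helix unit
    propagated into a slightly curved solenoid."""
    return RepeatSpec(
        h1=HelixParams(length=20), h2=HelixParams(length=20),
        intra_unit=SixDOF(tx=8.6, ty=4.8, tz=30.0, rx=180.0),
        inter_unit=SixDOF(ty=9.6, rz=-6.0),
        n_repeats=5)


@pytest.fixture(scope="session")
def demo_scaffold(demo_spec):
    return build_repeat_backbone(demo_spec)


@pytest.fixture(scope="session")
def planted_asn():
    model, idx = make_planted_bidentate()
    place_amide_hydrogens(model)
    return model, idx


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
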