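import numpy as np
import pytest

import tubulestage as ts
from tubulestage.backends import OracleBackend
from tubulestage.synth import MarkerRule, RenderParams


@pytest.fixture(scope="session")
def small_slide():
    """12-tubule synthetic slide with marker channels and ground truth."""
    params = RenderParams(
        markers={
            "sert_all": MarkerRule(positive_classes=frozenset({"Sert"})),
            "sert_early": MarkerRule(
                positive_classes=frozenset({"Sert"}),
                positive_stages=frozenset({"I-V", "VI-VIII"}),
            ),
        }
    )
    slide, ann, channels = ts.generate_slide(12, seed=3, params=params)
    return slide, ann, channels


@pytest.fixture(scope="session")
def oracle_result(small_slide):
    """Zero-noise oracle pipeline output on the session slide."""
    slide, ann, _ = small_slide
    return ts.analyze_slide(slide, OracleBackend(ann))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
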