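import math
from dataclasses import replace

import pytest

import cervidx as cx


@pytest.fixture(scope="session")
def risk_model():
    return cx.build_risk_model()


@pytest.fixture(scope="session")
def injury_model():
    return cx.build_injury_model()


def sized_spec(base: cx.ImageSpec, n_nuclei: int, seed: int, load: float = 0.12) -> cx.ImageSpec:
    """Frame the requested nucleus count at a conservative area load so
    rejection-sampled placement (with its separation margin) always fits."""
    side = max(480, int(math.sqrt(n_nuclei * base.area_dist[0] / load)))
    return replace(base, n_nuclei=n_nuclei, seed=seed, width=side, height=side)


@pytest.fixture(scope="session")
def worked_case_records():
    """The three published validation case records (age, sexual-onset age,
    partners, pregnancies, first-pregnancy age, STD, lesions)."""
    return {
        "normal": cx.ClinicalRecord(47, 23, 2, 1, 27, False, False),
        "agc": cx.ClinicalRecord(43, 16, 1, 7, 28, False, False),
        "positive": cx.ClinicalRecord(50, 19, 3, 7, 20, False, True),
    }
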