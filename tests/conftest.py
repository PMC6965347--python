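import pytest
from hypothesis import settings

from tpattern import (
    DetectionParams,
    EventSeries,
    EventType,
    PatternTemplate,
    TData,
    generate_noise_tdata,
    plant_pattern,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_tdata(T, **series):
    """Shorthand: make_tdata(100, a=[3, 9], b=[5])."""
    return TData(
        T=T,
        series=[
            EventSeries(EventType.from_label(lab), sorted(pts))
            for lab, pts in series.items()
        ],
    )


@pytest.fixture
def default_params():
    return DetectionParams()


@pytest.fixture
def planted_chain_fixture():
    """((A B) C) with gaps 5 and 7 planted 4 times among background noise:
    three involved series with 10 extra uniform points each plus five
    pure-noise series, T = 10^4."""
    noise = generate_noise_tdata(5, 10, 10_000, seed=3)
    data, truth = plant_pattern(
        noise,
        PatternTemplate(("A", "B", "C"), (5, 7), 4),
        seed=4,
        noise_points=10,
    )
    return data, truth
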