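import warnings

import pytest
from hypothesis import HealthCheck, settings

from domhier.data_model import Bird, DisplacementEvent

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("default")


@pytest.fixture
def quartet():
    """One family of four birds, one per treatment cell, 2M/2F."""
    return [
        Bird(id="A", family="f1", sex="M", amount="Plenty", effort="Easy", tarsus=29.5, weight=80.0, delta_tl=0.3),
        Bird(id="B", family="f1", sex="M", amount="Plenty", effort="Hard", tarsus=29.8, weight=78.0, delta_tl=-0.1),
        Bird(id="C", family="f1", sex="F", amount="Lean", effort="Easy", tarsus=28.3, weight=74.0, delta_tl=None),
        Bird(id="D", family="f1", sex="F", amount="Lean", effort="Hard", tarsus=28.9, weight=76.0, delta_tl=1.2),
    ]


@pytest.fixture
def substitute_family():
    """Three resident birds plus one treatment-matched substitute."""
    return [
        Bird(id="P", family="f2", sex="M", amount="Plenty", effort="Easy", tarsus=29.5, weight=80.0),
        Bird(id="Q", family="f2", sex="F", amount="Plenty", effort="Hard", tarsus=29.8, weight=78.0),
        Bird(id="R", family="f2", sex="F", amount="Lean", effort="Easy", tarsus=28.3, weight=74.0),
        Bird(id="S", family="f2", sex="M", amount="Lean", effort="Hard", tarsus=28.9, weight=76.0,
             is_substitute=True),
    ]


@pytest.fixture
def make_events():
    """Factory: list of (displacer, displaced) -> ordered events for one family."""

    def _make(pairs, family="f1", week=1, day=1, start_order=1):
        return [
            DisplacementEvent(family=family, week=week, day=day, video_order=start_order + i,
                              displacer=a, displaced=b)
            for i, (a, b) in enumerate(pairs)
        ]

    return _make


@pytest.fixture(autouse=True)
def _quiet_unobserved_dyad_warnings():
    """Most fixtures have unobserved dyads; silence that specific warning."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*never interacted.*")
        yield
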