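import numpy as np
import pytest

from mmgrowth import DivisionEvent, ObservationWindow


@pytest.fixture
def window25():
    """A 25 h observable window starting at 0, 5-min imaging grid."""
    return ObservationWindow(t_start=0.0, t_end=25.0)


@pytest.fixture
def default_window():
    """The study's analysis window: [15 h, 40 h], 5-min grid."""
    return ObservationWindow()


def make_events(taus, birth=0.0, channel="ch00"):
    """Events at given generation times, all born at the same time."""
    return [
        DivisionEvent(
            cell_id=f"cell{i}",
            channel_id=channel,
            birth_time=birth,
            generation_time=float(tau),
        )
        for i, tau in enumerate(taus)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
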