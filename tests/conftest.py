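import numpy as np
import pytest

from whistledialog.core import Channel, Condition, Dialog, WhistleEvent


def make_event(channel, onset, offset, amp=0.1):
    return WhistleEvent(channel, onset, offset, amp, amp)


def make_dialog(events, duration=60.0, **kwargs):
    defaults = dict(
        pair_id="p0",
        round_index=0,
        condition=Condition.COMPETITIVE,
        round_duration=duration,
        events=events,
    )
    defaults.update(kwargs)
    return Dialog(**defaults)


def random_dialog(rng, max_events=10, duration=60.0):
    """Random two-channel dialog with well-separated onsets."""
    n = int(rng.integers(0, max_events + 1))
    events = []
    t = 0.0
    last_offset = {Channel.A: None, Channel.B: None}
    for _ in range(n):
        ch = Channel.A if rng.random() < 0.5 else Channel.B
        t += float(rng.uniform(0.01, 1.0))
        onset = round(t, 2)
        prev = last_offset[ch]
        if prev is not None and onset < prev:
            onset = round(prev + 0.01, 2)  # keep one channel non-overlapping
        dur = round(float(rng.uniform(0.05, 0.6)), 2)
        if onset + dur > duration:
            break
        events.append(make_event(ch, onset, onset + dur))
        last_offset[ch] = onset + dur
        t = onset
    return make_dialog(events, duration=duration)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def hand_dialog():
    """Seven events, four utterances, hand-computed features (see test_features)."""
    events = [
        make_event(Channel.A, 0.0, 0.3, 0.12),
        make_event(Channel.A, 0.6, 0.8, 0.10),
        make_event(Channel.B, 1.0, 1.4, 0.20),
        make_event(Channel.B, 1.6, 1.8, 0.10),
        make_event(Channel.A, 1.7, 2.0, 0.30),
        make_event(Channel.B, 2.5, 2.8, 0.15),
        make_event(Channel.A, 3.1, 3.2, 0.10),
    ]
    return make_dialog(events, duration=4.0)
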