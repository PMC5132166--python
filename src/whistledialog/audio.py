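"""Whistle event extraction from waveforms and loudness equalization.

Detection is a plain amplitude-envelope pulse-train analysis: rectify,
smooth with a short moving average, threshold relative to the channel
peak with hysteresis, then merge events separated by less than
``min_gap`` and drop events shorter than ``min_event_duration``.

The module also renders event lists back to audio (sine bursts with a
trapezoidal envelope) so the detector can be exercised end-to-end
against ground truth, and reads/writes PCM WAV via :mod:`scipy.io.wavfile`.
"""

from __future__ import annotations

import dataclasses
import statistics
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

from .core import Channel, Dialog, WhistleEvent, replace_events

__all__ = [
    "DetectorParams",
    "detect_whistles",
    "equalize_loudness",
    "render_events",
    "render_dialog",
    "read_wav",
    "write_wav",
]

#: mean(|sin|) over a cycle; rectified-envelope calibration for sine carriers.
_SINE_RECTIFICATION = 2.0 / np.pi


@dataclass(frozen=True)
class DetectorParams:
    """Envelope detector configuration.

    ``threshold`` and ``hysteresis`` are fractions of the channel's peak
    envelope; an event opens when the envelope rises to ``threshold`` and
    closes when it falls below ``hysteresis``.
    """

    sample_rate: float = 8000.0
    envelope_window: float = 0.005
    threshold: float = 0.10
    hysteresis: float = 0.05
    min_event_duration: float = 0.020
    min_gap: float = 0.030

    def __post_init__(self) -> None:
        if not (0 < self.hysteresis < self.threshold <= 1):
            raise ValueError(
                "need 0 < hysteresis < threshold <= 1, got "
                f"hysteresis={self.hysteresis}, threshold={self.threshold}"
            )
        if self.min_event_duration <= 0:
            raise ValueError("min_event_duration must be > 0")
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


def envelope(waveform: np.ndarray, params: DetectorParams) -> np.ndarray:
    """Rectified waveform smoothed by a centered moving average.

    Scaled by pi/2 so a unit sine carrier yields a unit envelope.
    """
    x = np.abs(np.asarray(waveform, dtype=float))
    window = max(1, int(round(params.envelope_window * params.sample_rate)))
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same") / _SINE_RECTIFICATION


def detect_whistles(
    waveform: np.ndarray, params: DetectorParams, channel: Channel
) -> list[WhistleEvent]:
    """Extract whistle events from a mono waveform.

    Returns sorted, non-overlapping events with peak/mean amplitudes
    measured on the smoothed envelope.  All-zero input yields no events.
    """
    x = np.asarray(waveform, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite samples")
    env = envelope(x, params)
    peak = env.max() if env.size else 0.0
    if peak <= 0:
        return []
    hi = params.threshold * peak
    lo = params.hysteresis * peak

    above_hi = env >= hi
    above_lo = (env >= lo).astype(np.int8)
    # Hysteresis: an event is a run of the lo-mask that reaches hi somewhere
    # (opens at the hi crossing's run start, closes when falling below lo).
    intervals: list[tuple[int, int]] = []
    run_starts = np.flatnonzero(np.diff(np.r_[0, above_lo]) == 1)
    run_ends = np.flatnonzero(np.diff(np.r_[above_lo, 0]) == -1) + 1
    for start, end in zip(run_starts, run_ends):
        if above_hi[start:end].any():
            intervals.append((int(start), int(end)))

    # merge events separated by less than min_gap
    min_gap_n = params.min_gap * params.sample_rate
    merged: list[list[int]] = []
    for start, end in intervals:
        if merged and start - merged[-1][1] < min_gap_n:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    sr = params.sample_rate
    events = []
    for start, end in merged:
        onset, offset = start / sr, end / sr
        if offset - onset < params.min_event_duration:
            continue
        seg = env[start:end]
        events.append(
            WhistleEvent(
                channel=channel,
                onset=onset,
                offset=offset,
                peak_amplitude=float(seg.max()),
                mean_amplitude=float(seg.mean()),
            )
        )
    return events


def equalize_loudness(dialog: Dialog) -> Dialog:
    """Rescale each channel's amplitudes so mean whistle loudness matches.

    Each channel is multiplied by ``grand_mean / channel_mean`` of the
    per-whistle mean amplitudes, equalizing the two channels at the grand
    mean.  Timing and durations are untouched.
    """
    factors = {}
    means = {}
    for ch in (Channel.A, Channel.B):
        evs = dialog.channel_events(ch)
        if not evs:
            raise ValueError(f"channel {ch.value} has no events to equalize")
        means[ch] = statistics.fmean(ev.mean_amplitude for ev in evs)
    grand = (means[Channel.A] + means[Channel.B]) / 2
    for ch, mean in means.items():
        if mean <= 0:
            raise ValueError(f"channel {ch.value} has zero mean loudness")
        factors[ch] = grand / mean
    new_events = [
        dataclasses.replace(
            ev,
            peak_amplitude=ev.peak_amplitude * factors[ev.channel],
            mean_amplitude=ev.mean_amplitude * factors[ev.channel],
        )
        for ev in dialog.events
    ]
    return replace_events(dialog, new_events)


# ---------------------------------------------------------------------------
# Rendering (synthetic audio for end-to-end tests and playback stimuli)


def render_events(
    events: list[WhistleEvent],
    duration: float,
    sample_rate: float = 8000.0,
    carrier_hz: float = 997.0,
    ramp: float = 0.005,
) -> np.ndarray:
    """Render events as sine bursts with trapezoidal envelopes.

    Burst amplitude equals the event's ``mean_amplitude`` so the detector
    round-trips loudness (its envelope is sine-calibrated).
    """
    n = int(round(duration * sample_rate))
    out = np.zeros(n)
    t = np.arange(n) / sample_rate
    for ev in events:
        i0 = int(round(ev.onset * sample_rate))
        i1 = min(n, int(round(ev.offset * sample_rate)))
        if i1 <= i0:
            continue
        seg_t = t[i0:i1]
        burst = ev.mean_amplitude * np.sin(2 * np.pi * carrier_hz * seg_t)
        n_ramp = min((i1 - i0) // 2, max(1, int(round(ramp * sample_rate))))
        shape = np.ones(i1 - i0)
        shape[:n_ramp] = np.linspace(0, 1, n_ramp, endpoint=False)
        shape[-n_ramp:] = np.linspace(1, 0, n_ramp, endpoint=False)[::-1]
        out[i0:i1] += burst * shape
    return out


def render_dialog(
    dialog: Dialog, sample_rate: float = 8000.0, carrier_hz: tuple = (997.0, 1511.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Render both channels of a dialog; returns (waveform_A, waveform_B)."""
    wavs = []
    for ch, hz in zip((Channel.A, Channel.B), carrier_hz):
        wavs.append(
            render_events(
                dialog.channel_events(ch),
                duration=dialog.round_duration,
                sample_rate=sample_rate,
                carrier_hz=hz,
            )
        )
    return wavs[0], wavs[1]


def write_wav(path, waveform: np.ndarray, sample_rate: float) -> None:
    wavfile.write(path, int(sample_rate), waveform.astype(np.float32))


def read_wav(path) -> tuple[float, np.ndarray]:
    """Read a WAV file; integer PCM is rescaled to [-1, 1] floats.

    Stereo input is returned as shape (n, 2); split L/R for the two
    channels of a dialog.
    """
    rate, data = wavfile.read(path)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return float(rate), data
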