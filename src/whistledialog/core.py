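"""Domain types and turn-taking structure of a two-channel whistle dialog.

A dialog is a time-ordered sequence of whistle events on two channels
(``A`` and ``B``), one per participant.  The central structural notion is
the *utterance*: a maximal run of one participant's whistles that is not
interrupted by a whistle onset of the partner.  Everything downstream
(turn-taking gaps, overlap proportions, accentuation features) is defined
on top of this segmentation.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "Channel",
    "Condition",
    "WhistleEvent",
    "Dialog",
    "Utterance",
    "RoundOutcome",
    "UnresolvedReason",
    "segment_utterances",
    "turn_taking_gaps",
    "overlap_proportion",
    "score_round",
    "read_events_csv",
    "write_events_csv",
    "dialogs_to_frame",
]

#: Onsets closer than this are considered simultaneous and ordered A before B.
ONSET_TIE_TOL = 1e-3


class Channel(str, enum.Enum):
    A = "A"
    B = "B"

    @property
    def other(self) -> "Channel":
        return Channel.B if self is Channel.A else Channel.A


class Condition(str, enum.Enum):
    COMPETITIVE = "competitive"
    NON_COMPETITIVE = "non_competitive"


class UnresolvedReason(str, enum.Enum):
    BOTH_CLAIMED = "both_claimed"
    NONE_CLAIMED = "none_claimed"


@dataclass(frozen=True)
class WhistleEvent:
    """One detected whistle: channel, time support and amplitude summary.

    Amplitudes are arbitrary linear units; intervals are half-open
    ``[onset, offset)`` in seconds.
    """

    channel: Channel
    onset: float
    offset: float
    peak_amplitude: float = 1.0
    mean_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.offset <= self.onset:
            raise ValueError(
                f"offset must exceed onset ({self.onset} .. {self.offset})"
            )
        if self.peak_amplitude < 0 or self.mean_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _sort_key(event: WhistleEvent) -> tuple:
    # Quantize so that onsets within ONSET_TIE_TOL tie, then break by channel A < B.
    return (round(event.onset / ONSET_TIE_TOL), event.channel.value)


@dataclass
class Dialog:
    """One round of a whistle dialog: events on two channels plus outcome flags.

    ``claim_A``/``claim_B`` record who blew the whistle at round end to
    claim the reward; ``fair_A``/``fair_B`` hold the end-of-experiment
    fairness judgment of each participant (``None`` if not collected).
    """

    pair_id: str
    round_index: int
    condition: Condition
    round_duration: float
    events: list[WhistleEvent] = field(default_factory=list)
    claim_A: bool = False
    claim_B: bool = False
    fair_A: Optional[bool] = None
    fair_B: Optional[bool] = None
    winner_truth: Optional[Channel] = None  # ground truth label (synthetic data)

    def __post_init__(self) -> None:
        if self.round_index < 0:
            raise ValueError("round_index must be >= 0")
        if self.round_duration <= 0:
            raise ValueError("round_duration must be > 0")
        self.events = sorted(self.events, key=_sort_key)
        for ev in self.events:
            if ev.onset < 0 or ev.offset > self.round_duration + 1e-9:
                raise ValueError(
                    f"event [{ev.onset}, {ev.offset}) outside round "
                    f"[0, {self.round_duration}]"
                )

    def channel_events(self, channel: Channel) -> list[WhistleEvent]:
        return [ev for ev in self.events if ev.channel == channel]

    def claim(self, channel: Channel) -> bool:
        return self.claim_A if channel == Channel.A else self.claim_B

    def fairness(self, channel: Channel) -> Optional[bool]:
        return self.fair_A if channel == Channel.A else self.fair_B


@dataclass(frozen=True)
class Utterance:
    """A maximal run of one channel's whistles uninterrupted by the partner."""

    channel: Channel
    events: tuple[WhistleEvent, ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("utterance must contain at least one event")
        if any(ev.channel != self.channel for ev in self.events):
            raise ValueError("all events of an utterance share one channel")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onset(self) -> float:
        return self.events[0].onset

    @property
    def offset(self) -> float:
        return self.events[-1].offset

    def durations(self) -> list[float]:
        return [ev.duration for ev in self.events]


@dataclass(frozen=True)
class RoundOutcome:
    resolved: bool
    winner: Optional[Channel]
    agreement: bool
    unresolved_reason: Optional[UnresolvedReason] = None
    agreement_known: bool = True

    def __post_init__(self) -> None:
        if self.resolved and self.winner is None:
            raise ValueError("resolved round must have a winner")
        if self.agreement and not self.resolved:
            raise ValueError("agreement implies resolved")


def segment_utterances(dialog: Dialog) -> list[Utterance]:
    """Partition a dialog's events into utterances.

    A partner onset terminates the current utterance; streaming over
    events in onset order (ties: A before B), utterances are exactly the
    maximal same-channel runs.
    """
    utterances: list[Utterance] = []
    current: list[WhistleEvent] = []
    for ev in dialog.events:
        if current and ev.channel != current[0].channel:
            utterances.append(Utterance(current[0].channel, tuple(current)))
            current = []
        current.append(ev)
    if current:
        utterances.append(Utterance(current[0].channel, tuple(current)))
    return utterances


def turn_taking_gaps(
    dialog: Dialog, responder: Optional[Channel] = None
) -> list[float]:
    """Pauses between the end of one speaker's utterance and the partner's reply.

    One gap per channel-switch transition where the responder's first onset
    is at or after the previous speaker's last offset; overlapping
    transitions are excluded (they are counted by :func:`overlap_proportion`).
    If ``responder`` is given, only transitions answered by that channel
    are returned.
    """
    utterances = segment_utterances(dialog)
    gaps: list[float] = []
    for prev, nxt in zip(utterances, utterances[1:]):
        if responder is not None and nxt.channel != responder:
            continue
        gap = nxt.onset - prev.events[-1].offset
        if gap >= 0:
            gaps.append(gap)
    return gaps


def overlap_proportion(dialog: Dialog, channel: Channel) -> Optional[float]:
    """Fraction of ``channel``'s whistles starting inside a partner whistle.

    A whistle overlaps when its onset lies in some partner whistle's
    ``[onset, offset)`` interval.  Returns ``None`` when the channel
    emitted no whistles.
    """
    own = dialog.channel_events(channel)
    if not own:
        return None
    partner = dialog.channel_events(channel.other)
    n_overlap = 0
    for ev in own:
        if any(p.onset <= ev.onset < p.offset for p in partner):
            n_overlap += 1
    return n_overlap / len(own)


def score_round(dialog: Dialog) -> RoundOutcome:
    """Resolve a competitive round from its claim and fairness flags.

    Exactly one claim resolves the round; an agreement additionally needs
    the loser's fairness approval.  If the loser's judgment is missing the
    outcome is flagged ``agreement_known=False``.
    """
    if dialog.claim_A and dialog.claim_B:
        return RoundOutcome(False, None, False, UnresolvedReason.BOTH_CLAIMED)
    if not dialog.claim_A and not dialog.claim_B:
        return RoundOutcome(False, None, False, UnresolvedReason.NONE_CLAIMED)
    winner = Channel.A if dialog.claim_A else Channel.B
    loser_fair = dialog.fairness(winner.other)
    if loser_fair is None:
        return RoundOutcome(True, winner, False, None, agreement_known=False)
    return RoundOutcome(True, winner, bool(loser_fair), None)


# ---------------------------------------------------------------------------
# Event-table CSV interface

EVENT_COLUMNS = [
    "pair_id",
    "round_index",
    "condition",
    "channel",
    "onset_s",
    "offset_s",
    "peak_amp",
    "mean_amp",
    "claim",
    "fair",
]


def dialogs_to_frame(dialogs: Iterable[Dialog]) -> pd.DataFrame:
    """One row per whistle; claim/fair flags repeated per channel."""
    rows = []
    for d in dialogs:
        for ev in d.events:
            rows.append(
                {
                    "pair_id": d.pair_id,
                    "round_index": d.round_index,
                    "condition": d.condition.value,
                    "channel": ev.channel.value,
                    "onset_s": ev.onset,
                    "offset_s": ev.offset,
                    "peak_amp": ev.peak_amplitude,
                    "mean_amp": ev.mean_amplitude,
                    "claim": d.claim(ev.channel),
                    "fair": d.fairness(ev.channel),
                }
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events_csv(dialogs: Iterable[Dialog], path) -> None:
    dialogs_to_frame(dialogs).to_csv(path, index=False)


def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("", "nan", "none"):
        return None
    if text in ("true", "1", "t", "yes"):
        return True
    if text in ("false", "0", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean field value {value!r}")


def read_events_csv(path, round_duration: Optional[float] = None) -> list[Dialog]:
    """Load the event-table CSV back into :class:`Dialog` objects.

    ``round_duration`` defaults to the latest offset of each round,
    rounded up to the next second, when not supplied.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"event table {path} lacks columns: {missing}")
    dialogs = []
    for (pair_id, round_index), group in frame.groupby(
        ["pair_id", "round_index"], sort=True
    ):
        events = [
            WhistleEvent(
                Channel(row.channel),
                float(row.onset_s),
                float(row.offset_s),
                float(row.peak_amp),
                float(row.mean_amp),
            )
            for row in group.itertuples()
        ]
        claims = {}
        fairs = {}
        for ch in (Channel.A, Channel.B):
            sub = group[group["channel"] == ch.value]
            if len(sub):
                claims[ch] = bool(_parse_bool(sub["claim"].iloc[0]))
                fairs[ch] = _parse_bool(sub["fair"].iloc[0])
            else:
                claims[ch] = False
                fairs[ch] = None
        duration = round_duration
        if duration is None:
            duration = float(int(max(ev.offset for ev in events)) + 1)
        dialogs.append(
            Dialog(
                pair_id=str(pair_id),
                round_index=int(round_index),
                condition=Condition(group["condition"].iloc[0]),
                round_duration=duration,
                events=events,
                claim_A=claims[Channel.A],
                claim_B=claims[Channel.B],
                fair_A=fairs[Channel.A],
                fair_B=fairs[Channel.B],
            )
        )
    return dialogs


def replace_events(dialog: Dialog, events: Sequence[WhistleEvent]) -> Dialog:
    """A copy of ``dialog`` with a new event list."""
    return dataclasses.replace(dialog, events=list(events))
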