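"""Synthetic two-channel whistle dialogs, playback stimuli and listeners.

The generator emits strictly alternating utterances on channels A and B.
Per-whistle durations and loudness are log-normal; each utterance-initial
whistle receives a role-dependent accent increment; turn-taking pauses
are gamma; with probability ``overlap_prob`` a reply instead starts
inside the partner's final whistle.  Role whistle rates (whistles per
minute) are met by scaling utterance lengths per role and solving the
intra-utterance pause mean from the remaining time budget.

One integer seed reproduces a full dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .core import Channel, Condition, Dialog, Utterance, WhistleEvent

__all__ = [
    "GeneratorParams",
    "ListenerModel",
    "ListenerResponse",
    "generate_dialog",
    "generate_experiment",
    "move_longest",
    "synthesize_playback",
    "build_playback_dialog",
    "simulate_listeners",
]

CONFIDENCE_LEVELS = ("sure", "not_totally_sure", "not_sure")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for a target mean/sd."""
    if mean <= 0 or sd <= 0:
        raise ValueError("log-normal mean and sd must be > 0")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the dialog generator; defaults follow the study's regime
    (1-min rounds, 3–8 whistles per utterance, winner/loser contrasts in
    accentuation and whistle rate)."""

    seed: int = 0
    round_duration: float = 60.0
    utterance_length_range: tuple[int, int] = (3, 8)
    base_duration_mean: float = 0.24
    base_duration_sd: float = 0.08
    base_loudness_mean: float = 0.11
    base_loudness_sd: float = 0.03
    accent_delta_winner: float = 0.14
    accent_delta_loser: float = 0.07
    loudness_accent_delta_winner: float = 0.03
    loudness_accent_delta_loser: float = 0.04
    gap_shape: float = 2.0
    gap_scale: float = 0.7
    overlap_prob: float = 0.15
    rate_winner: float = 41.0
    rate_loser: float = 36.0
    intra_gap_shape: float = 2.0
    #: floor on within-utterance pauses; closer whistles would be heard
    #: (and detected) as one event
    min_intra_gap: float = 0.05
    #: floor on how deep an overlapping reply starts inside the partner's
    #: final whistle, keeping overlaps unambiguous after re-detection
    min_overlap_depth: float = 0.02

    def __post_init__(self) -> None:
        lo, hi = self.utterance_length_range
        if not (1 <= lo <= hi <= 20):
            raise ValueError("utterance_length_range must lie within [1, 20]")
        if not 0 <= self.overlap_prob <= 1:
            raise ValueError("overlap_prob must be in [0, 1]")
        for name in (
            "round_duration",
            "base_duration_mean",
            "base_duration_sd",
            "base_loudness_mean",
            "base_loudness_sd",
            "gap_shape",
            "gap_scale",
            "rate_winner",
            "rate_loser",
            "intra_gap_shape",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def gap_mean(self) -> float:
        return self.gap_shape * self.gap_scale

    def intra_gap_mean(self) -> float:
        """Mean intra-utterance pause that meets the requested whistle
        rates inside the round duration; raises if the rates cannot fit."""
        total_rate = self.rate_winner + self.rate_loser
        per_whistle = 60.0 / total_rate
        mean_len = sum(self.utterance_length_range) / 2.0
        accent_mean = (self.accent_delta_winner + self.accent_delta_loser) / 2.0
        budget = (
            per_whistle
            - self.base_duration_mean
            - accent_mean / mean_len
            - (1 - self.overlap_prob) * self.gap_mean / mean_len
            + self.overlap_prob * (self.base_duration_mean / 2.0) / mean_len
        )
        intra = budget / (1.0 - 1.0 / mean_len)
        if intra < 0.005:
            raise ValueError(
                f"whistle rates {self.rate_winner}+{self.rate_loser}/min do not "
                f"fit in {self.round_duration}s rounds (intra gap {intra:.4f}s)"
            )
        return intra


@dataclass(frozen=True)
class ListenerModel:
    p_choose_accentuated: float = 0.70
    confidence_probs: tuple[float, float, float] = (0.40, 0.44, 0.16)

    def __post_init__(self) -> None:
        if not 0 <= self.p_choose_accentuated <= 1:
            raise ValueError("p_choose_accentuated must be in [0, 1]")
        if abs(sum(self.confidence_probs) - 1.0) > 1e-9:
            raise ValueError("confidence_probs must sum to 1")


@dataclass(frozen=True)
class ListenerResponse:
    listener_id: int
    dialog_id: int
    choice: Channel
    confidence: str
    truth: Channel

    @property
    def correct(self) -> bool:
        return self.choice == self.truth


def _role_of(channel: Channel, winner: Channel) -> str:
    return "winner" if channel == winner else "loser"


def generate_dialog(
    params: GeneratorParams,
    winner: Channel = Channel.A,
    pair_id: str = "pair0",
    round_index: int = 0,
    condition: Condition = Condition.COMPETITIVE,
    rng: Optional[np.random.Generator] = None,
) -> Dialog:
    """One round of alternating utterances with a ground-truth winner.

    The winner channel gets the winner accent increments and the higher
    whistle rate; the winner claims the reward and the loser judges the
    distribution fair, so scoring yields an agreement.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dur_mu, dur_sigma = _lognormal_params(
        params.base_duration_mean, params.base_duration_sd
    )
    loud_mu, loud_sigma = _lognormal_params(
        params.base_loudness_mean, params.base_loudness_sd
    )
    lo, hi = params.utterance_length_range
    mean_len = (lo + hi) / 2.0
    rate_mean = (params.rate_winner + params.rate_loser) / 2.0
    intra_mean = params.intra_gap_mean()
    intra_scale = intra_mean / params.intra_gap_shape

    accent = {
        "winner": params.accent_delta_winner,
        "loser": params.accent_delta_loser,
    }
    loud_accent = {
        "winner": params.loudness_accent_delta_winner,
        "loser": params.loudness_accent_delta_loser,
    }
    rate = {"winner": params.rate_winner, "loser": params.rate_loser}

    events: list[WhistleEvent] = []
    channel = Channel.A if rng.random() < 0.5 else Channel.B
    t = float(rng.gamma(params.gap_shape, params.gap_scale)) * 0.5
    last_partner_dur = None
    while True:
        role = _role_of(channel, winner)
        scaled = float(rng.integers(lo, hi + 1)) * rate[role] / rate_mean
        # stochastic rounding keeps the per-role expected length exact
        n = int(scaled) + int(rng.random() < (scaled - int(scaled)))
        n = max(1, min(20, n))
        placed = 0
        for i in range(n):
            duration = float(rng.lognormal(dur_mu, dur_sigma))
            loudness = float(rng.lognormal(loud_mu, loud_sigma))
            if i == 0:
                duration += accent[role]
                loudness += loud_accent[role]
            if t + duration > params.round_duration:
                break
            events.append(
                WhistleEvent(
                    channel=channel,
                    onset=t,
                    offset=t + duration,
                    peak_amplitude=loudness,
                    mean_amplitude=loudness,
                )
            )
            t += duration
            placed += 1
            if i < n - 1:
                t += max(
                    params.min_intra_gap,
                    float(rng.gamma(params.intra_gap_shape, intra_scale)),
                )
        if placed < n or t >= params.round_duration:
            break
        last = events[-1]
        last_partner_dur = last.duration
        if rng.random() < params.overlap_prob:
            # reply starts inside the partner's final whistle
            depth_min = min(params.min_overlap_depth, last_partner_dur / 2)
            t = last.offset - float(rng.uniform(depth_min, last_partner_dur))
            t = max(t, last.onset + 1e-4)
        else:
            t = last.offset + max(
                params.min_intra_gap,
                float(rng.gamma(params.gap_shape, params.gap_scale)),
            )
        if t >= params.round_duration:
            break
        channel = channel.other
    if not events:
        raise ValueError("generator produced no events; parameters infeasible")
    return Dialog(
        pair_id=pair_id,
        round_index=round_index,
        condition=condition,
        round_duration=params.round_duration,
        events=events,
        claim_A=(winner == Channel.A),
        claim_B=(winner == Channel.B),
        fair_A=True,
        fair_B=True,
        winner_truth=winner,
    )


def generate_experiment(
    params: GeneratorParams,
    n_pairs: int,
    n_competitive: int = 3,
    n_noncompetitive: int = 2,
    noncompetitive_params: Optional[GeneratorParams] = None,
    p_winner_switch: float = 0.5,
) -> list[Dialog]:
    """A full dataset: per pair, non-competitive rounds (no role contrast)
    and competitive rounds with a per-round ground-truth winner.

    The first competitive winner is drawn uniformly; subsequent rounds
    switch winner with probability ``p_winner_switch``.
    """
    rng = np.random.default_rng(params.seed)
    if noncompetitive_params is None:
        # same base behaviour, no winner/loser contrast
        mid_accent = (params.accent_delta_winner + params.accent_delta_loser) / 2
        mid_loud = (
            params.loudness_accent_delta_winner + params.loudness_accent_delta_loser
        ) / 2
        mid_rate = (params.rate_winner + params.rate_loser) / 2
        noncompetitive_params = replace(
            params,
            accent_delta_winner=mid_accent,
            accent_delta_loser=mid_accent,
            loudness_accent_delta_winner=mid_loud,
            loudness_accent_delta_loser=mid_loud,
            rate_winner=mid_rate,
            rate_loser=mid_rate,
        )
    dialogs = []
    for p in range(n_pairs):
        pair_id = f"pair{p:03d}"
        round_index = 0
        for _ in range(n_noncompetitive):
            dialogs.append(
                generate_dialog(
                    noncompetitive_params,
                    winner=Channel.A,
                    pair_id=pair_id,
                    round_index=round_index,
                    condition=Condition.NON_COMPETITIVE,
                    rng=rng,
                )
            )
            round_index += 1
        winner = Channel.A if rng.random() < 0.5 else Channel.B
        for _ in range(n_competitive):
            dialogs.append(
                generate_dialog(
                    params,
                    winner=winner,
                    pair_id=pair_id,
                    round_index=round_index,
                    condition=Condition.COMPETITIVE,
                    rng=rng,
                )
            )
            round_index += 1
            if rng.random() < p_winner_switch:
                winner = winner.other
    return dialogs


# ---------------------------------------------------------------------------
# Accentuation playback construction


def move_longest(durations: Sequence[float], position: Literal["first", "middle"]):
    """Permute a whistle-duration sequence so the longest whistle sits at
    index 0 (``first``) or index floor(n/2) (``middle``); other whistles
    keep their relative order.  Ties pick the earliest original position."""
    values = list(durations)
    n = len(values)
    if n < 3:
        raise ValueError(f"utterance needs >= 3 whistles, got {n}")
    idx_longest = max(range(n), key=lambda i: (values[i], -i))
    target = 0 if position == "first" else n // 2
    rest = values[:idx_longest] + values[idx_longest + 1 :]
    return rest[:target] + [values[idx_longest]] + rest[target:]


def synthesize_playback(
    sequences: Sequence[Sequence[float]],
    position: Literal["first", "middle"],
    channel: Channel = Channel.A,
    amplitude: float = 0.1,
    intra_gap: float = 0.15,
    turn_gap: float = 1.0,
    start: float = 0.0,
) -> list[Utterance]:
    """Lay the permuted duration sequences out as timed utterances on one
    channel (constant amplitude: only positional accentuation differs
    between the ``first`` and ``middle`` variants)."""
    for seq in sequences:
        if not (3 <= len(seq) <= 8):
            raise ValueError(
                f"playback utterances need 3-8 whistles, got {len(seq)}"
            )
    utterances = []
    t = start
    for seq in sequences:
        permuted = move_longest(seq, position)
        events = []
        for i, dur in enumerate(permuted):
            events.append(
                WhistleEvent(channel, t, t + dur, amplitude, amplitude)
            )
            t += dur
            if i < len(permuted) - 1:
                t += intra_gap
        utterances.append(Utterance(channel, tuple(events)))
        t += turn_gap
    return utterances


def build_playback_dialog(
    sequences: Sequence[Sequence[float]],
    accent_channel: Channel = Channel.A,
    pair_id: str = "playback",
    round_index: int = 0,
    amplitude: float = 0.1,
    intra_gap: float = 0.15,
    turn_gap: float = 1.0,
) -> Dialog:
    """Interleave the two variants into one dialog: the accentuated channel
    plays each utterance in its longest-first version, the partner replies
    with the longest-in-middle version of the same whistles."""
    other = accent_channel.other
    events: list[WhistleEvent] = []
    t = 0.5
    for seq in sequences:
        for ch, position in ((accent_channel, "first"), (other, "middle")):
            utt = synthesize_playback(
                [seq], position, channel=ch, amplitude=amplitude,
                intra_gap=intra_gap, turn_gap=0.0, start=t,
            )[0]
            events.extend(utt.events)
            t = utt.offset + turn_gap
    return Dialog(
        pair_id=pair_id,
        round_index=round_index,
        condition=Condition.COMPETITIVE,
        round_duration=t + 1.0,
        events=events,
        claim_A=(accent_channel == Channel.A),
        claim_B=(accent_channel == Channel.B),
        fair_A=True,
        fair_B=True,
        winner_truth=accent_channel,
    )


# ---------------------------------------------------------------------------
# Listener simulation


def simulate_listeners(
    model: ListenerModel,
    n_listeners: int,
    n_dialogs: int,
    seed: int,
    truths: Optional[Sequence[Channel]] = None,
) -> list[ListenerResponse]:
    """Independent Bernoulli winner designations per listener-dialog.

    Each listener picks the accentuated (ground-truth winner) channel with
    probability ``p_choose_accentuated``; confidence is drawn independently
    from ``confidence_probs``.
    """
    rng = np.random.default_rng(seed)
    if truths is None:
        truths = [
            Channel.A if rng.random() < 0.5 else Channel.B
            for _ in range(n_dialogs)
        ]
    if len(truths) != n_dialogs:
        raise ValueError("truths length must equal n_dialogs")
    responses = []
    for listener in range(n_listeners):
        for dialog in range(n_dialogs):
            truth = truths[dialog]
            correct = rng.random() < model.p_choose_accentuated
            choice = truth if correct else truth.other
            confidence = CONFIDENCE_LEVELS[
                int(rng.choice(3, p=model.confidence_probs))
            ]
            responses.append(
                ListenerResponse(listener, dialog, choice, confidence, truth)
            )
    return responses
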