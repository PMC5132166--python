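"""Per-whistler acoustic variables and condition averaging.

Seven variables per whistler per round: mean loudness, mean duration,
whistle count, mean turn-taking gap, overlap proportion, and the two
positional accentuation measures (duration and loudness): the mean, over
utterances with at least two whistles, of first-whistle value minus the
mean of the following whistles' values.

Missing values stay missing (NaN) throughout — a silent channel or a
round without a multi-whistle utterance never fabricates a zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    Channel,
    Dialog,
    Utterance,
    overlap_proportion,
    segment_utterances,
    turn_taking_gaps,
)

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "accentuation",
    "compute_features",
    "features_frame",
    "condition_means",
    "accent_vs_cv",
]

FEATURE_NAMES = [
    "mean_loudness",
    "mean_duration",
    "n_whistles",
    "mean_turn_gap",
    "overlap_prop",
    "dur_accent",
    "loud_accent",
]

LoudnessAttr = Literal["mean", "peak"]


@dataclass(frozen=True)
class FeatureVector:
    mean_loudness: float
    mean_duration: float
    n_whistles: int
    mean_turn_gap: float
    overlap_prop: float
    dur_accent: float
    loud_accent: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _event_value(event, measure: str, loudness_attr: LoudnessAttr) -> float:
    if measure == "duration":
        return event.duration
    if measure == "loudness":
        return (
            event.mean_amplitude if loudness_attr == "mean" else event.peak_amplitude
        )
    raise ValueError(f"unknown measure {measure!r}")


def accentuation(
    utterances: Iterable[Utterance],
    measure: Literal["duration", "loudness"],
    loudness_attr: LoudnessAttr = "mean",
) -> float:
    """Mean over multi-whistle utterances of (first value − mean follower value).

    Single-whistle utterances are skipped; NaN when no utterance has a
    follower.
    """
    diffs = []
    for utt in utterances:
        if len(utt) < 2:
            continue
        values = [_event_value(ev, measure, loudness_attr) for ev in utt.events]
        diffs.append(values[0] - float(np.mean(values[1:])))
    return float(np.mean(diffs)) if diffs else math.nan


def compute_features(
    dialog: Dialog, loudness_attr: LoudnessAttr = "mean"
) -> dict[Channel, FeatureVector]:
    """The seven acoustic variables for each channel of one dialog."""
    utterances = segment_utterances(dialog)
    out = {}
    for ch in (Channel.A, Channel.B):
        events = dialog.channel_events(ch)
        own_utts = [u for u in utterances if u.channel == ch]
        if not events:
            out[ch] = FeatureVector(
                math.nan, math.nan, 0, math.nan, math.nan, math.nan, math.nan
            )
            continue
        gaps = turn_taking_gaps(dialog, responder=ch)
        ovl = overlap_proportion(dialog, ch)
        out[ch] = FeatureVector(
            mean_loudness=float(
                np.mean(
                    [_event_value(ev, "loudness", loudness_attr) for ev in events]
                )
            ),
            mean_duration=float(np.mean([ev.duration for ev in events])),
            n_whistles=len(events),
            mean_turn_gap=float(np.mean(gaps)) if gaps else math.nan,
            overlap_prop=ovl if ovl is not None else math.nan,
            dur_accent=accentuation(own_utts, "duration"),
            loud_accent=accentuation(own_utts, "loudness", loudness_attr),
        )
    return out


def _cv(values: list[float]) -> float:
    # sample (n-1) standard deviation over mean
    if len(values) < 2:
        return math.nan
    mean = float(np.mean(values))
    if mean == 0:
        return math.nan
    return float(np.std(values, ddof=1)) / mean


def features_frame(
    dialogs: Iterable[Dialog], loudness_attr: LoudnessAttr = "mean"
) -> pd.DataFrame:
    """One row per whistler-round: identifiers, the seven variables, and the
    coefficients of variation of per-whistle duration/loudness (used for the
    accentuation-vs-variability correlation)."""
    rows = []
    for d in dialogs:
        fvs = compute_features(d, loudness_attr)
        for ch, fv in fvs.items():
            events = d.channel_events(ch)
            rows.append(
                {
                    "pair_id": d.pair_id,
                    "round_index": d.round_index,
                    "condition": d.condition.value,
                    "channel": ch.value,
                    **fv.as_dict(),
                    "cv_duration": _cv([ev.duration for ev in events]),
                    "cv_loudness": _cv(
                        [_event_value(ev, "loudness", loudness_attr) for ev in events]
                    ),
                }
            )
    return pd.DataFrame(rows)


def condition_means(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-pair, per-condition feature means.

    Averages whistler-round values (both whistlers, all rounds of the
    condition) per pair, skipping missing entries; ``<feature>_n`` reports
    the effective count behind each mean.  A pair with no rounds in a
    condition simply has no row for it.
    """
    records = []
    for (pair_id, condition), group in frame.groupby(
        ["pair_id", "condition"], sort=True
    ):
        rec = {"pair_id": pair_id, "condition": condition}
        for name in FEATURE_NAMES:
            values = group[name].astype(float)
            valid = values.dropna()
            rec[name] = float(valid.mean()) if len(valid) else math.nan
            rec[f"{name}_n"] = int(len(valid))
        records.append(rec)
    return pd.DataFrame(records)


class RankCorrelation(NamedTuple):
    rho: float
    p_value: float
    n: int
    defined: bool


def accent_vs_cv(
    frame: pd.DataFrame, measure: Literal["duration", "loudness"] = "duration"
) -> RankCorrelation:
    """Spearman correlation between accentuation and the CV of per-whistle
    values, one observation per whistler-round."""
    accent_col = "dur_accent" if measure == "duration" else "loud_accent"
    cv_col = "cv_duration" if measure == "duration" else "cv_loudness"
    sub = frame[[accent_col, cv_col]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 complete observations, have {n}")
    x = sub[accent_col].to_numpy()
    y = sub[cv_col].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        return RankCorrelation(math.nan, math.nan, n, defined=False)
    rho, p = sps.spearmanr(x, y)
    return RankCorrelation(float(rho), float(p), n, defined=True)
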