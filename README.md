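# whistledialog

Analysis pipeline for two-channel whistle dialogs: pairs of participants
negotiate over a resource using only whistle sounds, one microphone per
participant. The package detects whistle events, segments utterances
(maximal runs of one participant's whistles uninterrupted by the
partner), computes per-whistler acoustic variables — loudness, duration,
whistle count, turn-taking gaps, overlap proportion, and the positional
accentuation of utterance-initial whistles — and runs the contest
statistics: paired signed-rank condition comparisons, binary mixed
models for agreement and winning success, and listener winner-designation
tests. A synthetic-dialog generator and an accentuation playback builder
make every stage testable end to end without recordings.

## Layout

- `whistledialog.core` — domain types (`WhistleEvent`, `Dialog`,
  `Utterance`, `RoundOutcome`), utterance segmentation, turn-taking
  gaps, overlap proportion, round scoring, event-table CSV I/O.
- `whistledialog.audio` — envelope-based whistle detection from WAV,
  loudness equalization, synthetic audio rendering.
- `whistledialog.features` — the seven per-whistler variables,
  per-pair condition means, accentuation-vs-variability correlation.
- `whistledialog.synthetic` — seeded dialog generator with ground-truth
  winner labels, accentuation playback construction (longest whistle
  first vs. in the middle), listener-response simulation.
- `whistledialog.stats` — Wilcoxon signed-rank with exact small-sample
  p, binomial z test, logistic mixed models (Gauss–Hermite ML, pair
  random intercept), crossed-random-effects listener concordance.
- `whistledialog.cli` — orchestration and the `whistledialog` command.

## CLI

```sh
# synthesize a dataset and write its event table
whistledialog simulate --seed 1 --n-pairs 45 --out-dir results

# detect whistles in stereo WAV recordings (one channel per whistler)
whistledialog detect --out-dir results recording1.wav recording2.wav

# per-whistler-round features from an event table
whistledialog features --events results/events.csv --out-dir results

# full contest analysis (simulate | events | wav input)
whistledialog analyze1 --seed 1 --n-pairs 45 --out-dir results

# playback selection, construction and listener-designation tests
whistledialog analyze2 --seed 1 --n-pairs 45 --out-dir results

# build accentuation playbacks from an event table
whistledialog playback --seed 1 --events results/events.csv --out-dir results
```

Reports are JSON/CSV files in the output directory; each embeds a hash
of the configuration that produced it, and a fixed seed reproduces a
run exactly.

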