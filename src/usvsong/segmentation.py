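"""Segment pixel traces into syllables and songs; frequency and crosstalk filters.

Rules (times in ms, intervals half-open [onset, offset)):

* elements separated by **less than 55 ms** of silence merge into one syllable
  ("separated by at least 55 ms" keeps them distinct);
* syllables separated by **less than 500 ms** belong to the same song;
* vocalisations with mean frequency **below 45 kHz** are excluded (they
  cluster around 20 kHz and are produced by unspecific exhaling, not true
  USV); the cutoff is strict, 45.0 kHz itself is kept;
* any syllable recorded simultaneously (positive temporal overlap) on more
  than one channel is removed from all channels involved — in a multi-
  compartment box the louder neighbour's call leaks through the partition, so
  attribution is unsafe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PixelTrace, Song, Syllable, concat_traces

__all__ = [
    "MIN_SYLLABLE_GAP_MS",
    "MIN_SONG_GAP_MS",
    "LOW_FREQ_CUTOFF_KHZ",
    "segment_syllables",
    "group_songs",
    "filter_low_frequency",
    "remove_crosstalk",
    "qc_frequency_summary",
]

MIN_SYLLABLE_GAP_MS = 55.0
MIN_SONG_GAP_MS = 500.0
LOW_FREQ_CUTOFF_KHZ = 45.0


def _mean_freq(trace: PixelTrace, weighted: bool = True) -> float:
    if weighted:
        tot = trace.amps.sum()
        if tot <= 0:
            return float(trace.freqs_khz.mean())
        return float((trace.freqs_khz * trace.amps).sum() / tot)
    return float(trace.freqs_khz.mean())


def segment_syllables(traces, min_gap_ms: float = MIN_SYLLABLE_GAP_MS,
                      weighted_mean: bool = True) -> list:
    """Merge elements closer than ``min_gap_ms`` into syllables, per channel.

    ``weighted_mean`` selects the amplitude-weighted centre of gravity as each
    syllable's mean frequency (the unweighted arithmetic mean is available for
    sensitivity checks).  Empty input yields an empty list.
    """
    by_channel: dict = {}
    for tr in traces:
        by_channel.setdefault(tr.channel, []).append(tr)
    out = []
    for ch in by_channel:
        chunk = sorted(by_channel[ch], key=lambda tr: tr.onset_ms)
        group = []
        for tr in chunk:
            if group and tr.onset_ms - group[-1].offset_ms < min_gap_ms:
                group.append(tr)
            else:
                if group:
                    out.append(_make_syllable(group, weighted_mean))
                group = [tr]
        if group:
            out.append(_make_syllable(group, weighted_mean))
    out.sort(key=lambda s: (s.channel, s.onset_ms))
    return out


def _make_syllable(group, weighted_mean: bool) -> Syllable:
    tr = concat_traces(group)
    return Syllable(trace=tr, mean_freq_khz=_mean_freq(tr, weighted_mean),
                    channel=tr.channel, syllable_id=tr.element_id)


def group_songs(syllables, min_gap_ms: float = MIN_SONG_GAP_MS) -> list:
    """Maximal runs of syllables with inter-syllable silences < ``min_gap_ms``.

    Syllables are grouped per channel; song ids are assigned in temporal order.
    """
    by_channel: dict = {}
    for s in syllables:
        by_channel.setdefault(s.channel, []).append(s)
    songs = []
    for ch in sorted(by_channel):
        run = []
        for s in sorted(by_channel[ch], key=lambda s: s.onset_ms):
            if run and s.onset_ms - run[-1].offset_ms >= min_gap_ms:
                songs.append(Song(syllables=run, song_id=f"{ch}-song{len(songs):04d}"))
                run = []
            run.append(s)
        if run:
            songs.append(Song(syllables=run, song_id=f"{ch}-song{len(songs):04d}"))
    return songs


def filter_low_frequency(syllables, cutoff_khz: float = LOW_FREQ_CUTOFF_KHZ):
    """Partition syllables into (kept, removed) by mean frequency.

    Syllables *strictly below* the cutoff are removed; both partitions are
    returned so the removal can be audited.
    """
    kept = [s for s in syllables if s.mean_freq_khz >= cutoff_khz]
    removed = [s for s in syllables if s.mean_freq_khz < cutoff_khz]
    return kept, removed


def remove_crosstalk(per_channel_syllables: dict):
    """Drop syllables that overlap in time with a syllable on another channel.

    ``per_channel_syllables`` maps channel -> syllable list.  Any positive
    overlap of the [onset, offset) intervals removes the element on *all*
    channels involved.  Returns ``(kept, removed)`` dicts of the same shape.
    A single channel passes through unchanged.
    """
    channels = list(per_channel_syllables)
    flagged = {ch: [False] * len(per_channel_syllables[ch]) for ch in channels}
    for i, ch_a in enumerate(channels):
        for ch_b in channels[i + 1:]:
            sa = per_channel_syllables[ch_a]
            sb = per_channel_syllables[ch_b]
            order_b = sorted(range(len(sb)), key=lambda j: sb[j].onset_ms)
            onsets_b = [sb[j].onset_ms for j in order_b]
            for ia, a in enumerate(sa):
                # candidates: b with onset < a.offset and offset > a.onset
                hi = np.searchsorted(onsets_b, a.offset_ms, side="left")
                for jb in order_b[:hi]:
                    b = sb[jb]
                    if b.offset_ms > a.onset_ms:
                        flagged[ch_a][ia] = True
                        flagged[ch_b][jb] = True
    kept = {ch: [s for s, f in zip(per_channel_syllables[ch], flagged[ch]) if not f]
            for ch in channels}
    removed = {ch: [s for s, f in zip(per_channel_syllables[ch], flagged[ch]) if f]
               for ch in channels}
    return kept, removed


def qc_frequency_summary(syllables) -> pd.DataFrame:
    """Per-syllable (min, max, mean) frequency table for the dichotomy check.

    Plotting minimum against maximum frequency separates true USV (>= 45 kHz)
    from the ~20 kHz exhaling cluster.
    """
    rows = [
        (s.syllable_id, s.channel, float(s.trace.freqs_khz.min()),
         float(s.trace.freqs_khz.max()), s.mean_freq_khz)
        for s in syllables
    ]
    return pd.DataFrame(rows, columns=["syllable_id", "channel", "min_freq",
                                       "max_freq", "mean_freq"])
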