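"""Core containers for tracked vocalisation contours and segmented units.

The pipeline operates on frequency-time-amplitude "pixel traces": the ridge of
a spectrogram tracked over time, one sample per instantaneous spectrum.  A
:class:`PixelTrace` is one continuous vocal element; elements separated by less
than the syllable gap merge into a :class:`Syllable`; bouts of syllables
separated by long silences form a :class:`Song`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["PixelTrace", "Syllable", "Song", "concat_traces"]


@dataclass
class PixelTrace:
    """Sampled frequency contour of one continuous vocal element.

    Parameters
    ----------
    times_ms:
        Sample times in milliseconds from recording start, strictly increasing.
    freqs_khz:
        Instantaneous peak frequency at each sample, kHz, all positive.
    amps:
        Amplitude of the tracked pixel at each sample (linear or dB, the
        weighting for the frequency centre of gravity).  Non-negative.
    """

    times_ms: np.ndarray
    freqs_khz: np.ndarray
    amps: np.ndarray
    element_id: str = ""
    channel: str = "ch0"

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.freqs_khz = np.asarray(self.freqs_khz, dtype=float)
        self.amps = np.asarray(self.amps, dtype=float)
        n = self.times_ms.size
        if n < 1:
            raise ValueError("a trace needs at least one sample")
        if self.freqs_khz.size != n or self.amps.size != n:
            raise ValueError("times, freqs and amps must have equal length")
        if n > 1 and not np.all(np.diff(self.times_ms) > 0):
            raise ValueError(f"times not strictly increasing in element {self.element_id!r}")
        if np.any(self.freqs_khz <= 0):
            raise ValueError(f"non-positive frequency in element {self.element_id!r}")

    @property
    def n(self) -> int:
        return self.times_ms.size

    @property
    def onset_ms(self) -> float:
        return float(self.times_ms[0])

    @property
    def offset_ms(self) -> float:
        return float(self.times_ms[-1])

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    def shifted(self, dt_ms: float) -> "PixelTrace":
        return replace(self, times_ms=self.times_ms + dt_ms)


@dataclass
class Syllable:
    """A single USV element (possibly merged from sub-elements < 55 ms apart)."""

    trace: PixelTrace
    mean_freq_khz: float
    channel: str = "ch0"
    syllable_id: str = ""
    individual: str = ""
    context: str = ""
    night: int = 0
    true_type13: Optional[str] = None  # ground truth when synthesised

    @property
    def onset_ms(self) -> float:
        return self.trace.onset_ms

    @property
    def offset_ms(self) -> float:
        return self.trace.offset_ms

    @property
    def duration_ms(self) -> float:
        return self.trace.duration_ms


@dataclass
class Song:
    """A bout of syllables; neighbouring songs are >= 500 ms apart."""

    syllables: list = field(default_factory=list)
    song_id: str = ""

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)

    @property
    def onset_ms(self) -> float:
        return self.syllables[0].onset_ms

    @property
    def offset_ms(self) -> float:
        return self.syllables[-1].offset_ms

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    @property
    def syllable_rate(self) -> float:
        """Syllables per second, count over span (a 1-syllable song uses its own duration)."""
        dur_s = self.duration_ms / 1000.0
        if dur_s <= 0:
            raise ValueError("song with zero duration")
        return self.n_syllables / dur_s

    def type_sequence(self, labels: Optional[dict] = None) -> list:
        """Ordered 13-type codes, from ground truth or a {syllable_id: code} map."""
        if labels is None:
            return [s.true_type13 for s in self.syllables]
        return [labels[s.syllable_id] for s in self.syllables]


def concat_traces(traces: list) -> PixelTrace:
    """Concatenate traces (sub-elements of one syllable) into one.

    Elements may overlap in time (e.g. a cross-channel duplicate on top of a
    native element); samples are time-sorted and, where two sounds coincide,
    the earlier-listed element's sample wins.
    """
    if len(traces) == 1:
        return traces[0]
    times = np.concatenate([t.times_ms for t in traces])
    freqs = np.concatenate([t.freqs_khz for t in traces])
    amps = np.concatenate([t.amps for t in traces])
    order = np.argsort(times, kind="stable")
    times, freqs, amps = times[order], freqs[order], amps[order]
    keep = np.concatenate([[True], np.diff(times) > 1e-9])
    return PixelTrace(
        times_ms=times[keep],
        freqs_khz=freqs[keep],
        amps=amps[keep],
        element_id=traces[0].element_id,
        channel=traces[0].channel,
    )
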