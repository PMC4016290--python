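"""Temporal and spectral syllable/song parameters.

Per syllable: duration, start frequency, least-squares frequency slope
(kHz/ms), minimum frequency, frequency band (max - min), amplitude-weighted
frequency centre of gravity (COG), and counts of frequency jumps and turns.

* A **jump** is a frequency change of at least 20 kHz accumulated over less
  than 4 contour samples (one sample standing in for one instantaneous
  spectrum; at the 0.5 ms default pitch the window is 1.5 ms).
* A **turn** is a direction reversal whose two legs each cover at least
  0.8 kHz in less than 3 ms.  Jump steps are masked out before turn detection
  so a step is never counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PixelTrace, Song

__all__ = [
    "JumpEvent",
    "TurnEvent",
    "SyllableFeatures",
    "frequency_cog",
    "detect_jumps",
    "detect_turns",
    "syllable_features",
    "song_features",
    "feature_table",
    "count_songs",
    "saturation_bootstrap",
]

JUMP_MIN_KHZ = 20.0
JUMP_MAX_WINDOW = 3        # steps ("less than 4 instantaneous FFT bins")
TURN_MIN_LEG_KHZ = 0.8
TURN_MAX_LEG_MS = 3.0      # each leg in *less than* 3 ms
SLOPE_THRESHOLD = 0.05     # kHz/ms for up/down modulation


@dataclass(frozen=True)
class JumpEvent:
    position: float   # fraction of syllable duration in [0, 1)
    direction: str    # "up" | "down"
    magnitude: float  # kHz, >= 20
    step_slice: tuple = (0, 0)  # [first, last] step index of the excursion


@dataclass(frozen=True)
class TurnEvent:
    position: float   # fraction of syllable duration
    shape: str        # "down-up" (U) | "up-down"


@dataclass(frozen=True)
class SyllableFeatures:
    duration: float      # ms
    freq_sta: float      # kHz at first sample
    freq_slope: float    # kHz/ms
    freq_min: float      # kHz
    freq_band: float     # kHz, max - min
    freq_cog: float      # kHz
    n_jumps: int
    n_turns: int
    jumps: tuple = ()
    turns: tuple = ()


def frequency_cog(trace: PixelTrace) -> float:
    """Amplitude-weighted mean frequency: sum(Freq_i Ampl_i) / sum(Ampl_i)."""
    if np.any(trace.amps < 0):
        raise ValueError("negative amplitudes")
    tot = trace.amps.sum()
    if tot <= 0:
        raise ValueError("all-zero amplitudes: centre of gravity undefined")
    return float((trace.freqs_khz * trace.amps).sum() / tot)


def detect_jumps(trace: PixelTrace, min_change_khz: float = JUMP_MIN_KHZ,
                 max_window_samples: int = JUMP_MAX_WINDOW) -> list:
    """Abrupt frequency steps: >= ``min_change_khz`` within <= ``max_window_samples``
    inter-sample steps.

    The contour's step sequence is split into maximal same-sign runs; a run
    containing a window of at most ``max_window_samples`` consecutive steps
    whose summed change reaches the threshold yields exactly one event,
    positioned at its largest step.  Overlapping qualifying windows therefore
    collapse into one event per monotone excursion.
    """
    f = trace.freqs_khz
    if f.size < 2:
        return []
    steps = np.diff(f)
    dur = trace.duration_ms
    t_mid = (trace.times_ms[:-1] + trace.times_ms[1:]) / 2.0 - trace.onset_ms
    events = []
    i = 0
    n = steps.size
    while i < n:
        s = np.sign(steps[i])
        j = i
        while j + 1 < n and np.sign(steps[j + 1]) == s and s != 0:
            j += 1
        if s != 0:
            run = np.abs(steps[i:j + 1])
            w = min(max_window_samples, run.size)
            csum = np.concatenate([[0.0], np.cumsum(run)])
            best = max(float(csum[k + w0] - csum[k])
                       for w0 in range(1, w + 1) for k in range(run.size - w0 + 1))
            if best >= min_change_khz:
                k_big = i + int(np.argmax(run))
                events.append(JumpEvent(
                    position=float(t_mid[k_big] / dur) if dur > 0 else 0.0,
                    direction="up" if s > 0 else "down",
                    magnitude=best,
                    step_slice=(i, j),
                ))
        i = j + 1
    return events


def detect_turns(trace: PixelTrace, min_leg_khz: float = TURN_MIN_LEG_KHZ,
                 max_leg_ms: float = TURN_MAX_LEG_MS, jumps=None) -> list:
    """Direction reversals with both legs >= ``min_leg_khz`` within < ``max_leg_ms``.

    A reversal is a local extremum of the contour; each leg magnitude is the
    largest frequency change between the extremum and any sample at most
    ``max_leg_ms`` (exclusive) away on that side, in the leg's direction.
    Steps belonging to jump events (pass ``jumps`` from :func:`detect_jumps`;
    recomputed if omitted) are masked: reversals whose legs touch a jump step
    are discarded.  Consecutive opposite reversals count separately.
    """
    f = trace.freqs_khz
    t = trace.times_ms
    if f.size < 3:
        return []
    if jumps is None:
        jumps = detect_jumps(trace)
    steps = np.diff(f)
    jump_step = np.zeros(steps.size, dtype=bool)
    for ev in jumps:
        a, b = ev.step_slice
        jump_step[a:b + 1] = True
    dur = trace.duration_ms
    events = []
    for k in range(1, f.size - 1):
        left = np.sign(f[k] - f[k - 1])
        if left == 0:
            # extend back over plateaus to find the incoming direction
            kk = k - 1
            while kk > 0 and f[kk] == f[kk - 1]:
                kk -= 1
            left = np.sign(f[kk] - f[kk - 1]) if kk > 0 else 0.0
        right = np.sign(f[k + 1] - f[k])
        if left == 0 or right == 0 or left == right:
            continue
        ok = True
        mags = []
        for side in (-1, +1):
            best = 0.0
            j = k + side
            while 0 <= j < f.size and abs(t[j] - t[k]) < max_leg_ms:
                lo, hi = min(j, k), max(j, k)
                if jump_step[lo:hi].any():
                    ok = False
                    break
                # change covered by the leg, measured in the leg's own direction
                change = (f[k] - f[j]) * left if side < 0 else (f[j] - f[k]) * right
                best = max(best, change)
                j += side
            mags.append(best)
            if not ok:
                break
        if ok and all(m >= min_leg_khz for m in mags):
            shape = "down-up" if left < 0 else "up-down"
            events.append(TurnEvent(position=float((t[k] - t[0]) / dur) if dur > 0 else 0.0,
                                    shape=shape))
    return events


def syllable_features(trace: PixelTrace, jump_min_khz: float = JUMP_MIN_KHZ,
                      jump_max_window: int = JUMP_MAX_WINDOW,
                      turn_min_leg_khz: float = TURN_MIN_LEG_KHZ,
                      turn_max_leg_ms: float = TURN_MAX_LEG_MS,
                      endpoint_slope: bool = False) -> SyllableFeatures:
    """All per-syllable parameters of one contour.

    The frequency slope is by default the least-squares fit of frequency on
    time (robust to contour jitter); ``endpoint_slope=True`` selects the
    endpoint difference divided by duration instead.
    """
    f = trace.freqs_khz
    t = trace.times_ms
    dur = trace.duration_ms
    if trace.n >= 2 and dur > 0:
        slope = float((f[-1] - f[0]) / dur) if endpoint_slope \
            else float(np.polyfit(t - t[0], f, 1)[0])
    else:
        slope = 0.0
    jumps = detect_jumps(trace, jump_min_khz, jump_max_window)
    turns = detect_turns(trace, turn_min_leg_khz, turn_max_leg_ms, jumps=jumps)
    return SyllableFeatures(
        duration=dur,
        freq_sta=float(f[0]),
        freq_slope=slope,
        freq_min=float(f.min()),
        freq_band=float(f.max() - f.min()),
        freq_cog=frequency_cog(trace),
        n_jumps=len(jumps),
        n_turns=len(turns),
        jumps=tuple(jumps),
        turns=tuple(turns),
    )


def song_features(song: Song) -> tuple:
    """(duration_ms, syllables_per_second) of a song."""
    return song.duration_ms, song.syllable_rate


def feature_table(syllables) -> pd.DataFrame:
    """One row per syllable: identifiers plus every syllable parameter.

    This is the export surface for downstream multivariate statistics
    (PERMANOVA, discriminant analysis), which are run in standard packages.
    """
    rows = []
    for s in syllables:
        ft = syllable_features(s.trace)
        rows.append({
            "syllable_id": s.syllable_id, "channel": s.channel,
            "individual": s.individual, "context": s.context, "night": s.night,
            "onset_ms": s.onset_ms, "offset_ms": s.offset_ms,
            "duration": ft.duration, "freq_sta": ft.freq_sta,
            "freq_slope": ft.freq_slope, "freq_min": ft.freq_min,
            "freq_band": ft.freq_band, "freq_cog": ft.freq_cog,
            "n_jumps": ft.n_jumps, "n_turns": ft.n_turns,
        })
    return pd.DataFrame(rows)


def count_songs(songs, individuals=None) -> pd.DataFrame:
    """Long-format song counts per (individual, context, night), zeros retained.

    ``individuals`` optionally lists every recorded mouse so that non-singers
    appear with count 0 (some mice never sing in any context).
    """
    rows = []
    for song in songs:
        s0 = song.syllables[0]
        if not s0.individual:
            raise ValueError(f"song {song.song_id!r} lacks individual metadata")
        rows.append((s0.individual, s0.context, s0.night))
    df = pd.DataFrame(rows, columns=["individual", "context", "night"])
    counts = (df.value_counts().rename("n_songs").reset_index()
              if len(df) else pd.DataFrame(columns=["individual", "context", "night", "n_songs"]))
    if individuals is not None:
        contexts = sorted(set(counts["context"])) or [""]
        nights = sorted(set(counts["night"])) or [0]
        full = pd.MultiIndex.from_product(
            [list(individuals), contexts, nights],
            names=["individual", "context", "night"])
        counts = (counts.set_index(["individual", "context", "night"])
                  .reindex(full, fill_value=0).reset_index())
        counts["n_songs"] = counts["n_songs"].astype(int)
    return counts.sort_values(["individual", "context", "night"]).reset_index(drop=True)


def saturation_bootstrap(songs_per_individual: dict, parameter,
                         ks=(6, 12, 18, 24, 30, 36), n_boot: int = 200, rng=None,
                         plateau_tol: float = 0.05) -> pd.DataFrame:
    """How many songs per night suffice: variance of a song parameter vs. k.

    For each individual with at least ``max(ks)`` songs, the variance of
    ``parameter(song)`` over the first k songs is computed for each k; the
    mean variance across individuals is bootstrap-resampled (over songs within
    individuals) for a confidence band.  The smallest k whose mean variance is
    within ``plateau_tol`` (relative) of the next k is flagged as the plateau
    — the point where analysing more songs stops adding information.

    ``parameter`` maps a :class:`~usvsong.core.Song` to a scalar (e.g.
    ``lambda s: s.duration_ms``).
    """
    if rng is None:
        rng = np.random.default_rng()
    ks = sorted(ks)
    eligible = {ind: s for ind, s in songs_per_individual.items() if len(s) >= ks[-1]}
    if not eligible:
        raise ValueError(f"no individual has >= {ks[-1]} songs")
    values = {ind: np.array([parameter(s) for s in songs[:ks[-1]]])
              for ind, songs in eligible.items()}
    rows = []
    mean_var = {}
    for k in ks:
        per_ind = np.array([np.var(v[:k], ddof=1) for v in values.values()])
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bv = [np.var(rng.choice(v[:k], size=k, replace=True), ddof=1)
                  for v in values.values()]
            boots[b] = float(np.mean(bv))
        mean_var[k] = float(per_ind.mean())
        rows.append({
            "k": k,
            "mean_variance": mean_var[k],
            "ci_low": float(np.quantile(boots, 0.025)),
            "ci_high": float(np.quantile(boots, 0.975)),
            "n_individuals": len(per_ind),
        })
    df = pd.DataFrame(rows)
    plateau_k = None
    for a, b in zip(ks, ks[1:]):
        denom = max(abs(mean_var[b]), 1e-12)
        if abs(mean_var[b] - mean_var[a]) / denom < plateau_tol:
            plateau_k = a
            break
    df.attrs["plateau_k"] = plateau_k
    return df
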