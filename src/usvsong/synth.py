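"""Synthetic USV corpus generator with ground-truth labels.

Generates pixel traces, syllables, songs and multi-channel recording sessions
whose statistics reproduce the published group parameters, so that every
downstream stage (segmentation, features, classification, syntax) can be
tested without the original recordings.

Shape templates
---------------
Each of the 13 syllable types is synthesised as a piecewise-linear frequency
contour built so that, noise-free, it satisfies exactly the defining criteria
of its type and of no more specific type (round trip: ``classify13`` of a
noise-free template returns the template's type).  Sampling is uniform at
``sample_interval_ms`` (default 0.5 ms); one sample stands in for one
instantaneous spectrum of the tracked spectrogram ridge.

Song timing
-----------
A song's type sequence is drawn from a group Markov model; inter-syllable
gaps lie in [55, 500) ms (shorter gaps would merge syllables, longer gaps
would split songs).  The published group means are means over a strongly
skewed song population — e.g. 20 syllables/s together with 505.9 ms mean
song duration is impossible for any single song once gaps are >= 55 ms — so
the generator calibrates a per-group mixture of brief single-syllable songs
and longer multi-syllable songs (see :class:`SongCalibration`) such that the
expected song duration and the expected per-song syllable rate both match the
published values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .core import PixelTrace, Song, Syllable
from .profiles import TYPE13, GroupProfile, calibrated_truncnorm
from .syntax import SyntaxModel, generate_mm, profile_syntax_model

__all__ = [
    "SynthesisConfig",
    "RecordingSession",
    "synth_syllable",
    "synth_song",
    "synth_session",
    "SongCalibration",
    "song_calibration",
]

# Minimum syllable duration (ms) needed to realise each template shape.
_TYPE_MIN_DUR = {
    "SFL": 6.0, "SDN": 6.0, "SUP": 6.0,
    "TDU": 12.0, "TUD": 12.0, "TRS": 16.0,
    "JED": 10.0, "JLD": 10.0, "JEU": 10.0, "JLU": 10.0,
    "JUD": 14.0, "JDU": 14.0, "JPS": 18.0,
}

_FREQ_LO, _FREQ_HI = 42.0, 122.0  # band the noise-free contours stay inside


@dataclass
class SynthesisConfig:
    """Plumbing parameters of the generator (not group statistics)."""

    sample_interval_ms: float = 0.5
    noise_sd_khz: float = 0.2     # SD of the smooth frequency jitter
    noise_smooth_ms: float = 2.0  # correlation scale of the jitter
    contaminant_rate: float = 0.0  # fraction of ~20 kHz non-USV elements
    crosstalk_rate: float = 0.0    # fraction of syllables mirrored on another channel
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_interval_ms <= 0:
            raise ValueError("sample_interval_ms must be positive")
        if not 0.0 <= self.contaminant_rate <= 1.0:
            raise ValueError("contaminant_rate must lie in [0, 1]")
        if not 0.0 <= self.crosstalk_rate <= 1.0:
            raise ValueError("crosstalk_rate must lie in [0, 1]")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")


# ---------------------------------------------------------------------------
# syllable templates
# ---------------------------------------------------------------------------

def _smooth_noise(n: int, sd: float, smooth_samples: float, rng) -> np.ndarray:
    """Zero-mean correlated jitter: Gaussian-filtered white noise rescaled to sd."""
    if sd <= 0 or n < 2:
        return np.zeros(n)
    w = rng.normal(0.0, 1.0, size=n)
    s = ndimage.gaussian_filter1d(w, sigma=max(smooth_samples, 1e-6), mode="nearest")
    s_sd = s.std()
    if s_sd <= 0:
        return np.zeros(n)
    return s * (sd / s_sd)


def _ramp(n: int, f0: float, slope_per_sample: float) -> np.ndarray:
    return f0 + slope_per_sample * np.arange(n)


def _turn_contour(n: int, dt: float, f0: float, first_down: bool, n_reversals: int,
                  rng) -> np.ndarray:
    """Piecewise contour with exactly ``n_reversals`` qualifying direction reversals.

    Every reversal is flanked on both sides by steep legs (|slope| ~ 0.9 kHz/ms
    for >= 2.5 ms, i.e. >= 2 kHz per leg, comfortably beyond the 0.8 kHz-in-3-ms
    criterion); gentle drift segments in between continue the current direction
    so no further reversals arise.
    """
    steep_slope = rng.uniform(0.75, 1.1)
    leg_ms = rng.uniform(2.6, 3.6)
    leg_n = max(int(round(leg_ms / dt)), int(math.ceil(2.6 / dt)))
    # segment pattern: drift(d), steep(d), steep(-d), drift(-d), steep(-d), steep(d), ...
    n_steep = 2 * n_reversals
    drift_total = n - n_steep * leg_n
    n_drift = n_reversals + 1
    if drift_total < 0:
        # too short for drift segments: shrink legs
        leg_n = max(2, n // n_steep)
        drift_total = max(n - n_steep * leg_n, 0)
    base = drift_total // n_drift
    drift_lens = [base] * n_drift
    drift_lens[-1] += drift_total - base * n_drift
    d = -1.0 if first_down else 1.0
    drift_slope = 0.06 * d
    steps = []
    for r in range(n_reversals):
        steps.append((drift_lens[r], drift_slope))
        steps.append((leg_n, steep_slope * np.sign(drift_slope)))
        steps.append((leg_n, -steep_slope * np.sign(drift_slope)))
        drift_slope = -drift_slope
    steps.append((drift_lens[-1], drift_slope))
    f = [f0]
    for seg_n, slope in steps:
        for _ in range(seg_n):
            if len(f) >= n:
                break
            f.append(f[-1] + slope * dt)
    while len(f) < n:
        f.append(f[-1] + drift_slope * dt)
    f = np.asarray(f[:n])
    # keep inside the band (shifts, never reshapes)
    f = f - max(0.0, f.max() - _FREQ_HI) + max(0.0, _FREQ_LO - f.min())
    return f


def _jump_contour(n: int, f0: float, jumps: list, rng) -> np.ndarray:
    """Flat segments joined by instantaneous steps.

    ``jumps`` is a list of (position_fraction, signed_magnitude_khz); each step
    lands between two consecutive samples, so it registers as a >= 20 kHz change
    within one inter-sample step.
    """
    f = np.full(n, f0)
    for frac, mag in jumps:
        k = int(round(frac * (n - 1)))
        k = min(max(k, 1), n - 1)
        f[k:] += mag
    lift = max(0.0, _FREQ_LO - f.min())
    drop = max(0.0, f.max() - _FREQ_HI)
    return f + lift - drop


def _sep_positions(fracs, n) -> bool:
    ks = sorted(int(round(fr * (n - 1))) for fr in fracs)
    return all(b - a >= 5 for a, b in zip(ks, ks[1:]))


def _template(type13: str, n: int, dt: float, f0: float, dur_ms: float, rng) -> np.ndarray:
    """Noise-free frequency contour of one syllable of the given 13-type."""
    if type13 == "SFL":
        return np.full(n, f0)
    if type13 in ("SUP", "SDN"):
        sign = 1.0 if type13 == "SUP" else -1.0
        headroom = (_FREQ_HI - f0) if sign > 0 else (f0 - _FREQ_LO)
        slope = rng.uniform(0.12, 0.55)
        slope = min(slope, max(0.9 * headroom / dur_ms, 0.0))
        slope = max(slope, 0.08)  # stay clear of the 0.05 kHz/ms threshold
        return _ramp(n, f0, sign * slope * dt)
    if type13 == "TDU":
        return _turn_contour(n, dt, f0, first_down=True, n_reversals=1, rng=rng)
    if type13 == "TUD":
        return _turn_contour(n, dt, f0, first_down=False, n_reversals=1, rng=rng)
    if type13 == "TRS":
        k = int(rng.integers(2, 4))
        return _turn_contour(n, dt, f0, first_down=bool(rng.integers(2)), n_reversals=k, rng=rng)
    # jump types: magnitudes kept >= 22 kHz (margin over the 20 kHz criterion)
    def up_mag(base):
        return min(rng.uniform(22.0, 32.0), _FREQ_HI - 2.0 - base)

    def down_mag(base):
        return min(rng.uniform(22.0, 32.0), base - _FREQ_LO - 2.0)

    if type13 in ("JEU", "JLU", "JED", "JLD"):
        early = type13 in ("JEU", "JED")
        frac = rng.uniform(0.15, 0.42) if early else rng.uniform(0.58, 0.85)
        if type13 in ("JEU", "JLU"):
            f0 = min(f0, _FREQ_HI - 26.0)
            mag = up_mag(f0)
        else:
            f0 = max(f0, _FREQ_LO + 26.0)
            mag = -down_mag(f0)
        return _jump_contour(n, f0, [(frac, mag)], rng)
    if type13 in ("JUD", "JDU"):
        for _ in range(20):
            fr1, fr2 = rng.uniform(0.12, 0.42), rng.uniform(0.58, 0.88)
            if _sep_positions([fr1, fr2], n):
                break
        if type13 == "JUD":
            f0 = min(f0, _FREQ_HI - 26.0)
            m1 = up_mag(f0)
            m2 = -down_mag(f0 + m1)
        else:
            f0 = max(f0, _FREQ_LO + 26.0)
            m1 = -down_mag(f0)
            m2 = up_mag(f0 + m1)
        return _jump_contour(n, f0, [(fr1, m1), (fr2, m2)], rng)
    if type13 == "JPS":
        # three alternating jumps (the "more than two jumps" catch-all)
        f0 = float(np.clip(f0, _FREQ_LO + 4.0, _FREQ_HI - 28.0))
        up_first = bool(rng.integers(2))
        for _ in range(40):
            fracs = np.sort(rng.uniform(0.10, 0.90, size=3))
            if _sep_positions(fracs, n):
                break
        mag = rng.uniform(22.0, 26.0)
        signs = [1, -1, 1] if up_first else [-1, 1, -1]
        # alternating equal steps keep the contour within [f0 - mag, f0 + mag]
        if not up_first and f0 - mag < _FREQ_LO + 2.0:
            f0 = _FREQ_LO + 2.0 + mag
        return _jump_contour(n, f0, [(fr, s * mag) for fr, s in zip(fracs, signs)], rng)
    raise ValueError(f"unknown 13-type code {type13!r}")


# per-profile cache of calibrated sampling distributions
_DIST_CACHE: dict = {}


def _profile_key(profile: GroupProfile) -> tuple:
    return profile.fingerprint()


def _duration_dist(profile: GroupProfile):
    key = ("dur", _profile_key(profile))
    if key not in _DIST_CACHE:
        p = profile.param("duration")
        _DIST_CACHE[key] = calibrated_truncnorm(p.mean, p.sd, low=6.0, high=p.mean + 8 * p.sd)
    return _DIST_CACHE[key]


def _freq_sta_dist(profile: GroupProfile):
    key = ("fsta", _profile_key(profile))
    if key not in _DIST_CACHE:
        p = profile.param("freq_sta")
        lo = max(46.0, p.mean - 4 * p.sd)
        hi = min(112.0, p.mean + 4 * p.sd)
        _DIST_CACHE[key] = calibrated_truncnorm(p.mean, p.sd, low=lo, high=hi)
    return _DIST_CACHE[key]


def synth_syllable(type13: str, profile: GroupProfile, config: SynthesisConfig, rng,
                   duration_ms: float = None, t0_ms: float = 0.0,
                   element_id: str = "e0", channel: str = "ch0",
                   f0_khz: float = None) -> PixelTrace:
    """One labelled syllable trace of the given 13-type.

    Duration and start frequency are drawn from the profile (truncated normals
    calibrated so the sampled means equal the group means); the noise-free
    contour satisfies exactly the defining criteria of ``type13``.  Smooth
    frequency jitter of SD ``config.noise_sd_khz`` is added on top (set it to 0
    for exact round-trip classification).
    """
    if type13 not in TYPE13:
        raise ValueError(f"unknown 13-type code {type13!r}")
    dt = config.sample_interval_ms
    if duration_ms is None:
        duration_ms = float(_duration_dist(profile).ppf(rng.random()))
    duration_ms = max(duration_ms, _TYPE_MIN_DUR[type13])
    n = max(int(round(duration_ms / dt)) + 1, 2)
    f0 = float(_freq_sta_dist(profile).ppf(rng.random())) if f0_khz is None else f0_khz
    freqs = _template(type13, n, dt, f0, duration_ms, rng)
    freqs = freqs + _smooth_noise(n, config.noise_sd_khz, config.noise_smooth_ms / dt, rng)
    x = np.linspace(0.0, 1.0, n)
    amps = 0.25 + 0.75 * np.sin(np.pi * np.clip(x, 0.02, 0.98))  # soft onset/offset envelope
    times = t0_ms + dt * np.arange(n)
    return PixelTrace(times_ms=times, freqs_khz=np.maximum(freqs, 1.0), amps=amps,
                      element_id=element_id, channel=channel)


# ---------------------------------------------------------------------------
# song-level calibration
# ---------------------------------------------------------------------------

_GAP_MIN, _GAP_MAX = 56.0, 489.0  # working range; hard limits are [55, 500)


@dataclass
class SongCalibration:
    """Solved knobs making E[song duration] and E[syllables/s] match the profile.

    ``delta_single`` — mean duration (ms) of the syllable of single-syllable
    songs (brief isolated chirps dominate the published per-song rate mean);
    ``beta_multi`` — scale on the profile syllable-duration law inside
    multi-syllable songs; ``mu_d_star`` — location of the target-duration law
    from which each multi-syllable song draws its intended total duration.
    """

    delta_single: float
    beta_multi: float
    mu_d_star: float
    length_pmf: np.ndarray = field(repr=False, default=None)


def _qgrid(dist, n=601) -> np.ndarray:
    """Quantile grid of a frozen distribution for fast expectations."""
    q = np.linspace(0.5 / n, 1 - 0.5 / n, n)
    return dist.ppf(q)


def _min_groups(profile: GroupProfile):
    """Distinct template minimum durations with their usage weights."""
    groups: dict = {}
    for t, u in zip(TYPE13, profile.type_probs):
        groups[_TYPE_MIN_DUR[t]] = groups.get(_TYPE_MIN_DUR[t], 0.0) + u
    return sorted(groups.items())


def _single_moments(delta: float, profile: GroupProfile):
    """E[duration] and E[1000/duration] of single-syllable songs."""
    dist = calibrated_truncnorm(delta, 0.3 * delta, low=6.0, high=delta * 2.5)
    g = _qgrid(dist)
    e_d = e_r = 0.0
    for mn, w in _min_groups(profile):
        d = np.maximum(g, mn)
        e_d += w * d.mean()
        e_r += w * (1000.0 / d).mean()
    return e_d, e_r


def _multi_syllable_mean(beta: float, profile: GroupProfile) -> float:
    p = profile.param("duration")
    dist = calibrated_truncnorm(beta * p.mean, max(beta * p.sd, 1.0), low=5.0,
                                high=beta * (p.mean + 8 * p.sd))
    g = _qgrid(dist)
    return float(sum(w * np.maximum(g, mn).mean() for mn, w in _min_groups(profile)))


def _song_moments(x: np.ndarray, profile: GroupProfile, pmf: np.ndarray):
    """Analytic (quantile-grid) E[duration] and E[rate] of the song mixture."""
    delta, beta, mu_star = x
    sigma_d = profile.param("song_duration").sd
    e_d1, e_r1 = _single_moments(delta, profile)
    mu_syll = _multi_syllable_mean(beta, profile)
    star = calibrated_truncnorm(mu_star, sigma_d, low=40.0, high=mu_star + 8 * sigma_d)
    gstar = _qgrid(star)
    e_d = pmf[0] * e_d1
    e_r = pmf[0] * e_r1
    for k in range(2, pmf.size + 1):
        pk = pmf[k - 1]
        if pk <= 0:
            continue
        m_k = k * mu_syll
        gap_tot = np.clip(gstar - m_k, _GAP_MIN * (k - 1), _GAP_MAX * (k - 1))
        dur = m_k + gap_tot
        e_d += pk * dur.mean()
        e_r += pk * (1000.0 * k / dur).mean()
    return e_d, e_r


def _solve_knobs(profile: GroupProfile, pmf: np.ndarray, target_d: float,
                 target_r: float, x0) -> SongCalibration:
    mu_d = profile.param("song_duration").mean
    mu_r = profile.param("syllable_rate").mean

    def resid(x):
        e_d, e_r = _song_moments(x, profile, pmf)
        return [(e_d - target_d) / mu_d, (e_r - target_r) / mu_r, 0.02 * (x[1] - 0.8)]

    sol = optimize.least_squares(
        resid, x0=x0,
        bounds=([8.0, 0.25, 60.0], [250.0, 1.3, 6000.0]),
        xtol=1e-9, ftol=1e-11,
    )
    return SongCalibration(*sol.x, length_pmf=pmf)


def _song_dists(profile: GroupProfile, cal: SongCalibration):
    """The three frozen duration laws implied by a calibration."""
    p = profile.param("duration")
    sigma_d = profile.param("song_duration").sd
    single = calibrated_truncnorm(cal.delta_single, 0.3 * cal.delta_single, low=6.0,
                                  high=cal.delta_single * 2.5)
    beta = cal.beta_multi
    multi = calibrated_truncnorm(beta * p.mean, max(beta * p.sd, 1.0), low=5.0,
                                 high=beta * (p.mean + 8 * p.sd))
    star = calibrated_truncnorm(cal.mu_d_star, sigma_d, low=40.0,
                                high=cal.mu_d_star + 8 * sigma_d)
    return single, multi, star


def _song_timing(types, profile, cal, rng):
    """Clamped syllable durations and gaps for one song; shared by the
    generator and the calibration simulation."""
    n = len(types)
    single, multi, star = _song_dists(profile, cal)
    if n == 1:
        d = max(float(single.ppf(rng.random())), _TYPE_MIN_DUR[types[0]])
        return [d], []
    draws = multi.ppf(rng.random(n))
    durs = [max(float(d), _TYPE_MIN_DUR[t]) for d, t in zip(draws, types)]
    d_star = float(star.ppf(rng.random()))
    g = float(np.clip((d_star - sum(durs)) / (n - 1), _GAP_MIN, _GAP_MAX))
    a = min(4.0, g - 55.05, 499.9 - g)  # symmetric jitter, mean preserved
    gaps = list(g + rng.uniform(-a, a, size=n - 1))
    return durs, gaps


def _simulate_song_moments(profile, model, cal, n_songs: int, rng):
    """Realised E[duration] and E[rate] from a timing-only simulation."""
    from .syntax import generate_mm
    seqs = generate_mm(model, n_songs, rng)
    dt = 0.5  # trace sampling quantises each syllable duration to the grid
    durs = np.empty(n_songs)
    rates = np.empty(n_songs)
    for i, seq in enumerate(seqs):
        ds, gaps = _song_timing(seq, profile, cal, rng)
        ds = [round(d / dt) * dt for d in ds]
        total = sum(ds) + sum(gaps)
        durs[i] = total
        rates[i] = 1000.0 * len(seq) / total
    return float(durs.mean()), float(rates.mean())


def song_calibration(profile: GroupProfile) -> SongCalibration:
    """Solve the generator knobs for one group (cached; deterministic).

    An analytic moment solve (quantile grids, first-order in the within-song
    duration spread) is followed by up to two correction rounds against a
    timing-only simulation that absorb the remaining Jensen bias of
    E[n/duration]; the simulation uses a
    fixed internal seed, so the calibration is a deterministic function of the
    profile.
    """
    key = ("songcal", _profile_key(profile))
    if key in _DIST_CACHE:
        return _DIST_CACHE[key]
    model = profile_syntax_model(profile)
    pmf = model.length_pmf()
    mu_d = profile.param("song_duration").mean
    mu_r = profile.param("syllable_rate").mean
    target_d, target_r = mu_d, mu_r
    x0 = [25.0, 0.8, max(mu_d, 120.0)]
    cal = None
    for _ in range(4):
        cal = _solve_knobs(profile, pmf, target_d, target_r, x0)
        x0 = [cal.delta_single, cal.beta_multi, cal.mu_d_star]
        sim_d, sim_r = _simulate_song_moments(
            profile, model, cal, 20000, np.random.default_rng(123456789))
        if abs(sim_d - mu_d) < 0.006 * mu_d and abs(sim_r - mu_r) < 0.006 * mu_r:
            break
        target_d += 0.9 * (mu_d - sim_d)
        target_r += 0.9 * (mu_r - sim_r)
    _DIST_CACHE[key] = cal
    return cal


def synth_song(profile: GroupProfile, model: SyntaxModel = None,
               config: SynthesisConfig = None, rng=None, t0_ms: float = 0.0,
               song_id: str = "s0", individual: str = "", context: str = "",
               night: int = 0, channel: str = "ch0") -> Song:
    """One song: type sequence from the Markov model, timing from the calibration.

    Single-syllable songs use the brief single-chirp duration law; songs with
    n >= 2 syllables draw a target total duration and distribute the remainder
    over n - 1 gaps, each confined to [55, 500) ms.  Ground-truth type labels
    are attached to every syllable.
    """
    if config is None:
        config = SynthesisConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if model is None:
        model = profile_syntax_model(profile)
    if not set(model.alphabet) <= set(TYPE13):
        raise ValueError("model alphabet must be a subset of the 13 type codes")
    cal = song_calibration(profile)
    types = generate_mm(model, 1, rng)[0]
    durs, gaps = _song_timing(types, profile, cal, rng)
    f0s = _freq_sta_dist(profile).ppf(rng.random(len(types)))
    syllables = []
    t = t0_ms
    for i, (code, d) in enumerate(zip(types, durs)):
        tr = synth_syllable(code, profile, config, rng, duration_ms=d, t0_ms=t,
                            element_id=f"{song_id}-e{i}", channel=channel,
                            f0_khz=float(f0s[i]))
        w = tr.amps / tr.amps.sum()
        syllables.append(
            Syllable(trace=tr, mean_freq_khz=float(w @ tr.freqs_khz), channel=channel,
                     syllable_id=tr.element_id, individual=individual, context=context,
                     night=night, true_type13=code)
        )
        t = tr.offset_ms + (gaps[i] if i < len(gaps) else 0.0)
    return Song(syllables=syllables, song_id=song_id)


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

@dataclass
class RecordingSession:
    """Multi-channel synthetic recording: traces per channel plus ground truth."""

    channel_traces: dict          # channel -> list of PixelTrace
    manifest: pd.DataFrame        # MANIFEST_COLUMNS; type13 == "NOISE" marks contaminants
    songs: dict                   # channel -> list of Song

    def write(self, out_dir) -> None:
        from pathlib import Path

        from .io import write_manifest, write_pixel_csv
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for ch, traces in self.channel_traces.items():
            write_pixel_csv(traces, out / f"{ch}.csv")
        write_manifest(self.manifest, out / "manifest.csv")


def _songs_per_night(profile: GroupProfile, rng) -> int:
    """Over-dispersed per-night song count: negative binomial matched to mean/SD.

    Counts of songs per individual and night are far more spread than Poisson
    (SD of the same order as, or larger than, the mean), so a negative binomial
    with moments matched to the profile is used; if the printed SD is below the
    Poisson limit, a Poisson is used instead.
    """
    p = profile.param("songs_per_night")
    mean, var = p.mean, p.sd ** 2
    if var <= mean:
        return max(1, int(rng.poisson(mean)))
    r = mean ** 2 / (var - mean)
    prob = r / (r + mean)
    return max(1, int(rng.negative_binomial(r, prob)))


def synth_session(profiles, config: SynthesisConfig = None, rng=None,
                  context: str = "DiffSex", night: int = 1,
                  n_songs: int = None) -> RecordingSession:
    """A multi-channel recording session with ground-truth manifest.

    One channel per profile entry (``profiles`` is a list of (individual_id,
    GroupProfile) pairs or bare profiles; ``config.n_channels`` must match).
    Each channel holds a night's worth of songs separated by > 500 ms, plus
    ~20 kHz broadband contaminants at ``config.contaminant_rate`` (fraction of
    elements) and, at ``config.crosstalk_rate``, syllables mirrored onto a
    neighbouring channel with overlapping timing.
    """
    if config is None:
        config = SynthesisConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pairs = []
    for i, pr in enumerate(profiles):
        if isinstance(pr, GroupProfile):
            pairs.append((f"ind{i}", pr))
        else:
            pairs.append((str(pr[0]), pr[1]))
    if len(pairs) != config.n_channels:
        raise ValueError("one profile per channel required")

    channel_traces: dict = {}
    songs_by_ch: dict = {}
    rows = []
    for ch_idx, (ind, profile) in enumerate(pairs):
        ch = f"ch{ch_idx}"
        model = profile_syntax_model(profile)
        count = n_songs if n_songs is not None else _songs_per_night(profile, rng)
        t = 1000.0 * rng.uniform(0.5, 2.0)
        traces = []
        ch_songs = []
        for s in range(count):
            sid = f"{ch}-s{s:04d}"
            song = synth_song(profile, model, config, rng, t0_ms=t, song_id=sid,
                              individual=ind, context=context, night=night, channel=ch)
            ch_songs.append(song)
            for syl in song.syllables:
                traces.append(syl.trace)
                rows.append((syl.trace.element_id, ch, ind, profile.population,
                             profile.sex, context, night, sid, syl.true_type13))
            t = song.offset_ms + rng.uniform(700.0, 3000.0)
            # contaminants: low-frequency exhaling sounds between songs
            p_cont = min(config.contaminant_rate / max(1 - config.contaminant_rate, 1e-9), 1.0)
            n_cont = rng.binomial(song.n_syllables, p_cont) if config.contaminant_rate > 0 else 0
            for c in range(n_cont):
                dur = rng.uniform(20.0, 80.0)
                nn = int(round(dur / config.sample_interval_ms)) + 1
                fr = rng.normal(20.0, 2.0) + _smooth_noise(nn, 1.0, 4.0, rng)
                eid = f"{ch}-noise{s:04d}-{c}"
                tr = PixelTrace(times_ms=t + config.sample_interval_ms * np.arange(nn),
                                freqs_khz=np.clip(fr, 8.0, 35.0),
                                amps=np.full(nn, 0.5), element_id=eid, channel=ch)
                traces.append(tr)
                rows.append((eid, ch, ind, profile.population, profile.sex,
                             context, night, "", "NOISE"))
                t = tr.offset_ms + rng.uniform(700.0, 2000.0)
        channel_traces[ch] = traces
        songs_by_ch[ch] = ch_songs

    # cross-channel duplicates: the same call picked up in a neighbouring compartment
    if config.crosstalk_rate > 0 and config.n_channels >= 2:
        for ch_idx in range(config.n_channels):
            ch = f"ch{ch_idx}"
            other = f"ch{(ch_idx + 1) % config.n_channels}"
            extra = []
            for song in songs_by_ch[ch]:
                for syl in song.syllables:
                    if rng.random() < config.crosstalk_rate:
                        tr = syl.trace
                        dup = PixelTrace(
                            times_ms=tr.times_ms + rng.uniform(-2.0, 2.0),
                            freqs_khz=tr.freqs_khz + rng.normal(0, 0.1, tr.n),
                            amps=tr.amps * rng.uniform(0.2, 0.6),
                            element_id=tr.element_id + "-x", channel=other)
                        extra.append(dup)
                        row = next(r for r in rows if r[0] == tr.element_id)
                        rows.append((dup.element_id, other) + row[2:])
            channel_traces[other] = sorted(
                channel_traces[other] + extra, key=lambda tr: tr.onset_ms)

    from .io import MANIFEST_COLUMNS
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return RecordingSession(channel_traces=channel_traces, manifest=manifest,
                            songs=songs_by_ch)
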