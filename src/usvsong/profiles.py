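"""Group parameter profiles for the four wild-mouse populations x sexes.

Two wild-derived *Mus musculus domesticus* populations (French, FRA; German,
GER) differ in their ultrasonic song repertoires.  Each population x sex group
is summarised by (a) means and standard deviations of temporal and spectral
song/syllable parameters and (b) probabilities to use, start with, or stop
with each of 13 syllable types.  These profiles parameterise the synthetic
corpus generator so that every downstream stage can be exercised and the
published group statistics recovered by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TYPE13",
    "TYPE5",
    "TYPE13_TO_TYPE5",
    "FeatureParam",
    "GroupProfile",
    "builtin_profiles",
    "calibrated_truncnorm",
]

#: The 13 syllable-type codes, in canonical table order.
TYPE13 = (
    "SFL", "SDN", "SUP",            # simple: flat / down / up
    "TDU", "TUD", "TRS",            # turns: down-up (U), up-down, multi
    "JED", "JLD", "JDU", "JEU", "JLU", "JUD", "JPS",  # jumps
)

TYPE5 = ("Simple", "Down", "Up", "Turn", "Jump")

TYPE13_TO_TYPE5 = {
    "SFL": "Simple", "SDN": "Down", "SUP": "Up",
    "TDU": "Turn", "TUD": "Turn", "TRS": "Turn",
    "JED": "Jump", "JLD": "Jump", "JDU": "Jump", "JEU": "Jump",
    "JLU": "Jump", "JUD": "Jump", "JPS": "Jump",
}


@dataclass(frozen=True)
class FeatureParam:
    mean: float
    sd: float


@dataclass(frozen=True, eq=False)
class GroupProfile:
    """Per-group parameter set: feature moments plus 13-type probability vectors."""

    population: str  # "FRA" | "GER"
    sex: str         # "f" | "m"
    feature_params: dict  # name -> FeatureParam
    type_probs: np.ndarray   # usage p, order TYPE13
    start_probs: np.ndarray  # p_Sta
    stop_probs: np.ndarray   # p_Sto (per-sequence: fraction of songs ending in type)

    def __post_init__(self) -> None:
        for name in ("type_probs", "start_probs", "stop_probs"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (13,) or np.any(v < 0):
                raise ValueError(f"{name} must be a non-negative 13-vector")
            s = v.sum()
            if s <= 0:
                raise ValueError(f"{name} sums to zero")
            object.__setattr__(self, name, v / s)
        for name, p in self.feature_params.items():
            if p.sd < 0:
                raise ValueError(f"negative SD for {name}")

    @property
    def label(self) -> str:
        return f"{self.population}/{self.sex}"

    def fingerprint(self) -> tuple:
        """Hashable identity of all numeric content (for caching solved models)."""
        fp = tuple(sorted((k, v.mean, v.sd) for k, v in self.feature_params.items()))
        return (self.population, self.sex, fp, self.type_probs.tobytes(),
                self.start_probs.tobytes(), self.stop_probs.tobytes())

    def param(self, name: str) -> FeatureParam:
        return self.feature_params[name]


# Published group statistics: mean (SD) per group, groups ordered
# (GER/f, GER/m, FRA/f, FRA/m).  Units: durations ms, frequencies kHz,
# slope kHz/ms, rates 1/s, counts per syllable or night.
_FEATURE_TABLE = {
    "songs_per_night":   [(20.3, 14.5), (12.53, 13.74), (17.2, 14.3), (14.6, 45.8)],
    "song_duration":     [(505.9, 382.9), (300.3, 181.0), (565.3, 479.4), (294.0, 183.4)],
    "syllable_rate":     [(20.0, 17.6), (29.25, 18.2), (25.6, 14.5), (31.8, 20.9)],
    "duration":          [(69.4, 36.5), (46.3, 36.5), (50.6, 36.4), (36.5, 26.0)],
    "freq_sta":          [(78.4, 8.2), (80.1, 14.2), (76.3, 10.8), (81.5, 18.6)],
    "freq_slope":        [(0.1, 0.3), (0.2, 0.5), (0.1, 0.5), (0.1, 0.6)],
    "freq_min":          [(68.6, 11.4), (75.0, 14.0), (65.3, 11.1), (75.5, 18.5)],
    "freq_band":         [(23.0, 14.4), (14.5, 10.6), (22.9, 14.3), (15.1, 14.4)],
    "freq_cog":          [(78.1, 10.6), (82.6, 13.3), (75.6, 9.8), (83.6, 18.8)],
    "jumps":             [(0.6, 0.9), (0.1, 0.4), (0.8, 1.1), (0.2, 0.5)],
    "turns":             [(2.0, 1.8), (1.2, 1.5), (2.0, 2.2), (0.9, 1.1)],
}

# Syllable-type probabilities per group: columns (p, p_Sta, p_Sto) for each of
# (GER/f, GER/m, FRA/f, FRA/m); rows in TYPE13 order.
_TYPE_TABLE = {
    #        GER/f               GER/m               FRA/f               FRA/m
    "SFL": [(0.05, 0.10, 0.09), (0.04, 0.02, 0.06), (0.05, 0.09, 0.11), (0.09, 0.12, 0.12)],
    "SDN": [(0.03, 0.06, 0.07), (0.05, 0.07, 0.06), (0.03, 0.03, 0.06), (0.11, 0.14, 0.14)],
    "SUP": [(0.33, 0.44, 0.47), (0.46, 0.54, 0.57), (0.29, 0.50, 0.49), (0.38, 0.30, 0.35)],
    "TDU": [(0.01, 0.01, 0.02), (0.03, 0.03, 0.03), (0.03, 0.05, 0.07), (0.04, 0.06, 0.06)],
    "TUD": [(0.11, 0.16, 0.10), (0.15, 0.19, 0.14), (0.09, 0.16, 0.11), (0.20, 0.17, 0.24)],
    "TRS": [(0.16, 0.12, 0.17), (0.12, 0.09, 0.10), (0.06, 0.06, 0.02), (0.08, 0.11, 0.05)],
    "JED": [(0.10, 0.00, 0.00), (0.09, 0.03, 0.02), (0.15, 0.03, 0.04), (0.02, 0.05, 0.00)],
    "JLD": [(0.03, 0.06, 0.01), (0.02, 0.01, 0.00), (0.05, 0.03, 0.03), (0.05, 0.03, 0.00)],
    "JDU": [(0.05, 0.02, 0.04), (0.02, 0.00, 0.00), (0.10, 0.00, 0.02), (0.00, 0.00, 0.00)],
    "JEU": [(0.00, 0.00, 0.00), (0.00, 0.00, 0.01), (0.01, 0.00, 0.00), (0.02, 0.03, 0.05)],
    "JLU": [(0.00, 0.00, 0.00), (0.00, 0.00, 0.00), (0.01, 0.00, 0.00), (0.01, 0.00, 0.00)],
    "JUD": [(0.00, 0.00, 0.00), (0.00, 0.00, 0.00), (0.01, 0.00, 0.00), (0.00, 0.00, 0.00)],
    "JPS": [(0.12, 0.02, 0.02), (0.00, 0.01, 0.00), (0.12, 0.04, 0.04), (0.00, 0.00, 0.00)],
}

_GROUPS = (("GER", "f"), ("GER", "m"), ("FRA", "f"), ("FRA", "m"))


def builtin_profiles() -> dict:
    """The four built-in population x sex profiles, keyed ``"GER/f"`` etc.

    Probability vectors are normalised (printed columns sum to 0.98-1.01 due
    to rounding).
    """
    out = {}
    for g, (pop, sex) in enumerate(_GROUPS):
        fp = {name: FeatureParam(*vals[g]) for name, vals in _FEATURE_TABLE.items()}
        cols = np.array([_TYPE_TABLE[t][g] for t in TYPE13], dtype=float)
        out[f"{pop}/{sex}"] = GroupProfile(
            population=pop,
            sex=sex,
            feature_params=fp,
            type_probs=cols[:, 0],
            start_probs=cols[:, 1],
            stop_probs=cols[:, 2],
        )
    return out


def calibrated_truncnorm(target_mean: float, sd: float, low: float, high: float = np.inf):
    """Cached front end of :func:`_calibrated_truncnorm`; see there."""
    return _calibrated_truncnorm(round(float(target_mean), 9), round(float(sd), 9),
                                 round(float(low), 9), round(float(high), 9))


@lru_cache(maxsize=8192)
def _calibrated_truncnorm(target_mean: float, sd: float, low: float, high: float):
    """A truncated normal on [low, high] whose *truncated* mean equals ``target_mean``.

    Sampling a plain normal truncated at physical bounds shifts its mean (for a
    heavily skewed case like syllable duration 36.5 +/- 26 ms bounded below, by
    several ms), which would bias every simulated group mean.  We therefore
    solve for the location parameter such that the mean after truncation is
    exactly the target.

    Returns a frozen ``scipy.stats.truncnorm`` distribution.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not (low < target_mean < high):
        raise ValueError("target mean must lie inside the truncation bounds")

    def tmean_minus_target(loc: float) -> float:
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    # the truncated mean is increasing in loc; expand the bracket downward until
    # it straddles the target (for sd >> target - low the location sits far in
    # the tail; scipy's truncnorm is tail-stable)
    lo = max(target_mean - 8 * sd, low - 6 * sd)
    for _ in range(40):
        if tmean_minus_target(lo) < 0:
            break
        lo -= 4 * sd
    loc = optimize.brentq(tmean_minus_target, lo, target_mean + 8 * sd, xtol=1e-10)
    a, b = (low - loc) / sd, (high - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)
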